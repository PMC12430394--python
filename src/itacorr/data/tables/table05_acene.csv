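# Acene series: HF/6-311++G(d,p) descriptors (a.u., scales as printed) vs
# MP2/6-311++G(d,p) correlation energy eps_mp2 (hartree). Verbatim
# transcription; R^2/RMSD footer rows omitted.
# scales: {"IF": 1e3, "SGBP": 1e3, "E2": 1e3, "E3": 1e3}
n,SS,IF,SGBP,E2,E3,R2r,R3r,G1,G2,G3,eps_mp2
2,70.395,2.489,0.460,0.316,11.207,69.910,73.784,-34.722,25.645,88.981,-1.3706
3,94.598,3.478,0.636,0.442,15.688,96.553,101.740,-47.666,35.408,123.979,-1.9146
4,118.807,4.468,0.811,0.569,20.169,123.195,129.691,-60.602,45.077,158.965,-2.4603
5,143.022,5.457,0.987,0.695,24.651,149.835,157.637,-73.547,54.729,193.946,-3.0070
6,167.241,6.447,1.162,0.821,29.133,176.474,185.576,-86.480,64.373,228.921,-3.5550
7,191.461,7.436,1.338,0.948,33.614,203.111,213.512,-99.419,74.020,263.894,-4.1036
8,215.675,8.426,1.513,1.074,38.096,229.747,241.444,-112.348,83.657,298.878,-4.6531
9,239.894,9.415,1.689,1.200,42.578,256.382,269.372,-125.278,93.298,333.853,-5.2030
10,264.114,10.405,1.865,1.326,47.059,283.016,297.298,-138.209,102.944,368.828,-5.7535
11,288.484,11.394,2.040,1.453,51.543,309.627,325.167,-151.260,112.708,404.117,-6.3415
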