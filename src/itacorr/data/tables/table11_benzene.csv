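# Benzene (C6H6)_n cluster series (n = 4-14): HF/6-311++G(d,p) descriptors
# (a.u., scales as printed) vs MP2/6-311++G(d,p) correlation energy eps_mp2
# (hartree). Verbatim transcription; R^2/RMSD footer rows omitted.
# scales: {"IF": 1e3, "SGBP": 1e3, "E3": 1e3}
n,SS,IF,SGBP,E2,E3,R2r,R3r,G1,G3,eps_mp2
4,182.943,5.993,1.136,759.350,26.923,172.970,183.096,-87.149,221.627,-3.3760
5,228.316,7.490,1.420,948.919,33.629,216.208,228.869,-108.820,277.997,-4.2330
6,273.691,8.987,1.703,1138.819,40.367,259.454,274.657,-130.621,334.386,-5.0898
7,318.886,10.483,1.987,1328.458,47.078,302.685,320.404,-152.252,391.102,-5.9553
8,364.310,11.980,2.270,1518.321,53.807,345.919,366.163,-174.079,447.714,-6.8098
9,409.374,13.477,2.554,1708.000,60.526,389.160,411.955,-195.780,504.763,-7.6758
10,454.744,14.974,2.838,1897.903,67.261,432.383,457.676,-217.571,561.267,-8.5359
11,500.069,16.471,3.121,2087.468,73.973,475.630,503.477,-239.230,617.793,-9.3921
12,545.054,17.967,3.404,2277.421,80.708,518.879,549.286,-261.020,675.525,-10.2656
13,589.963,19.462,3.688,2467.339,87.442,562.104,595.025,-282.767,733.570,-11.1408
14,635.264,20.959,3.971,2656.842,94.148,605.328,640.753,-304.418,789.848,-12.0021
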