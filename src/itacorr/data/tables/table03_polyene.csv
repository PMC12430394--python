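# Polyene series: HF/6-311++G(d,p) descriptors (a.u., scales as printed) vs
# MP2/6-311++G(d,p) correlation energy eps_mp2 (hartree). Verbatim transcription;
# R^2/RMSD footer rows omitted.
# scales: {"IF": 1e3, "SGBP": 1e3, "E3": 1e3}
n,SS,IF,SGBP,E2,E3,R2r,R3r,G1,G3,eps_mp2
1,22.069,0.510,0.109,63.427,2.243,16.638,17.935,-8.846,18.948,-0.2910
2,37.486,1.010,0.204,126.732,4.489,31.067,33.236,-16.196,37.205,-0.5659
3,52.876,1.510,0.298,189.930,6.726,45.493,48.534,-23.495,55.289,-0.8423
4,68.260,2.009,0.393,253.162,8.967,59.918,63.824,-30.808,73.409,-1.1192
5,83.643,2.509,0.488,316.406,11.209,74.342,79.111,-38.125,91.575,-1.3964
6,99.023,3.009,0.583,379.653,13.451,88.766,94.397,-45.438,109.749,-1.6737
7,114.403,3.509,0.677,442.902,15.693,103.190,109.682,-52.756,127.925,-1.9510
8,129.783,4.008,0.772,506.150,17.934,117.613,124.967,-60.070,146.103,-2.2285
9,145.163,4.508,0.867,569.399,20.176,132.037,140.251,-67.385,164.282,-2.5059
10,160.542,5.008,0.962,632.647,22.418,146.460,155.536,-74.701,182.461,-2.7834
30,468.132,15.003,2.856,1897.616,67.253,434.930,461.224,-221.004,546.043,-8.3329
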