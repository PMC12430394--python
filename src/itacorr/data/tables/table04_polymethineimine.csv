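# All-trans-polymethineimine series: HF/6-311++G(d,p) descriptors (a.u., scales
# as printed) vs MP2/6-311++G(d,p) correlation energy eps_mp2 (hartree).
# Verbatim transcription; R^2/RMSD footer rows omitted. The IF column is
# transcribed exactly as printed (its magnitudes indicate an implicit 10^3
# scale despite the unscaled column header).
# scales: {"SGBP": 1e3}
n,SS,IF,SGBP,E2,E3,R2r,R3r,G3,eps_mp2
1,17.891,0.602,0.109,84.234,4.138,16.585,17.767,17.765,-0.3219
2,29.226,1.194,0.204,168.281,8.272,30.918,32.784,35.058,-0.6255
3,40.534,1.786,0.300,252.322,12.406,45.247,47.797,52.420,-0.9295
4,51.834,2.377,0.395,336.418,16.546,59.576,62.805,69.772,-1.2337
5,63.128,2.969,0.490,420.432,20.675,73.905,77.814,87.181,-1.5377
6,74.418,3.561,0.585,504.457,24.806,88.234,92.823,104.601,-1.8416
7,85.706,4.152,0.680,588.488,28.940,102.564,107.833,121.973,-2.1454
8,96.990,4.744,0.775,672.535,33.072,116.894,122.845,139.422,-2.4491
9,108.273,5.336,0.871,756.623,37.210,131.224,137.857,156.850,-2.7527
10,119.552,5.927,0.966,840.677,41.345,145.555,152.870,174.241,-3.0563
20,232.308,11.844,1.917,1681.135,82.670,288.867,303.008,348.833,-6.0907
30,345.014,17.761,2.869,2521.373,123.976,432.195,453.192,523.649,-9.1245
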