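# Polyyne series: HF/6-311++G(d,p) descriptors (a.u., scales as printed) vs
# MP2/6-311++G(d,p) correlation energy eps_mp2 (hartree). Verbatim transcription
# of the published table (repeat counts n = 1-10, 30); the R^2/RMSD footer rows
# and a stray trailing value in the R^2 row are omitted.
# scales: {"IF": 1e3, "SGBP": 1e3, "E3": 1e3}
n,SS,IF,SGBP,E2,E3,R2r,R3r,G1,G3,IG,eps_mp2
1,17.116,0.503,0.096,63.341,2.251,14.478,15.411,-6.702,13.889,0.253,-0.2718
2,27.503,0.996,0.178,126.454,4.498,26.687,28.049,-11.822,26.724,0.357,-0.5284
3,37.877,1.489,0.260,189.565,6.744,38.891,40.680,-16.946,39.589,0.458,-0.7879
4,48.238,1.982,0.342,252.682,8.991,51.093,53.301,-22.064,52.468,0.556,-1.0485
5,58.604,2.475,0.425,315.797,11.238,63.292,65.918,-27.186,65.335,0.654,-1.3100
6,68.968,2.968,0.507,378.914,13.485,75.491,78.532,-32.303,78.206,0.751,-1.5715
7,79.331,3.461,0.589,442.032,15.731,87.690,91.146,-37.422,91.079,0.849,-1.8332
8,89.696,3.954,0.671,505.147,17.978,99.888,103.759,-42.541,103.952,0.946,-2.0952
9,100.063,4.447,0.753,568.264,20.225,112.086,116.372,-47.659,116.821,1.043,-2.3570
10,110.435,4.940,0.835,631.378,22.472,124.284,128.984,-52.780,129.686,1.139,-2.6192
30,317.730,14.800,2.478,1893.708,67.408,368.246,381.243,-155.141,387.180,3.076,-7.8579
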