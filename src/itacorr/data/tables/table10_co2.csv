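# (CO2)_n cluster series (n = 4-40): HF/6-311++G(d,p) descriptors (a.u., scales
# as printed) vs RI-MP2/6-311++G(d,p) correlation energy eps_mp2 (hartree).
# Verbatim transcription; R^2/RMSD footer rows omitted. Note: the printed rows
# n = 22 and n = 23 carry identical E2/E3 values (4.275 / 3.342) — an apparent
# typographical duplication, transcribed as printed.
# scales: {"IF": 1e3, "SGBP": 1e3, "E2": 1e3, "E3": 1e5}
n,SS,IF,SGBP,E2,E3,R2r,R3r,G3,eps_mp2
4,35.676,4.618,0.604,0.777,0.608,90.119,94.242,87.199,-2.0780
5,44.343,5.772,0.755,0.972,0.760,112.597,117.629,110.311,-2.6020
6,52.975,6.925,0.905,1.166,0.911,135.124,141.177,133.364,-3.1251
7,61.551,8.078,1.056,1.360,1.063,157.664,164.803,156.231,-3.6531
8,70.225,9.232,1.207,1.555,1.215,180.182,188.320,179.164,-4.1772
9,78.890,10.385,1.357,1.749,1.367,202.688,211.805,202.144,-4.7008
10,87.459,11.538,1.508,1.943,1.519,225.201,235.323,225.314,-5.2286
11,96.066,12.691,1.659,2.138,1.671,247.744,258.928,248.319,-5.7533
12,104.630,13.845,1.810,2.332,1.823,270.253,282.434,271.861,-6.2824
13,113.096,14.997,1.960,2.526,1.975,292.762,305.941,295.591,-6.8152
14,121.760,16.151,2.111,2.721,2.127,315.271,329.437,318.380,-7.3397
15,130.261,17.303,2.262,2.915,2.279,337.783,352.939,342.101,-7.8683
16,138.809,18.456,2.412,3.110,2.431,360.299,376.486,365.340,-8.3948
17,147.426,19.610,2.563,3.304,2.582,382.823,400.036,388.562,-8.9212
18,155.935,20.763,2.714,3.498,2.734,405.331,423.523,411.987,-9.4509
19,164.464,21.916,2.864,3.692,2.886,427.851,447.048,435.461,-9.9779
20,173.049,23.069,3.015,3.887,3.039,450.351,470.533,458.492,-10.5090
21,181.681,24.222,3.166,4.081,3.190,472.899,494.173,481.566,-11.0351
22,190.085,25.375,3.316,4.275,3.342,495.391,517.595,505.485,-11.5638
23,198.669,26.528,3.467,4.275,3.342,517.900,541.108,528.669,-12.0920
24,207.333,27.681,3.618,4.470,3.494,540.447,564.742,551.542,-12.6201
25,215.912,28.834,3.768,4.664,3.645,562.977,588.305,575.132,-13.1445
26,224.348,29.987,3.919,4.858,3.797,585.450,611.697,598.457,-13.6717
27,232.942,31.140,4.069,5.053,3.950,607.998,635.332,621.629,-14.2075
28,241.311,32.292,4.220,5.247,4.102,630.486,658.742,646.216,-14.7384
29,249.849,33.445,4.371,5.441,4.253,653.028,682.370,669.245,-15.2667
30,258.485,34.598,4.521,5.636,4.405,675.542,705.876,692.513,-15.7929
31,266.924,35.751,4.672,5.830,4.557,698.031,729.325,716.064,-16.3268
32,275.455,36.904,4.823,6.025,4.709,720.528,752.779,739.801,-16.8616
33,283.987,38.057,4.973,6.219,4.861,743.042,776.303,763.194,-17.3899
34,292.460,39.209,5.124,6.413,5.013,765.584,799.882,786.656,-17.9154
35,301.250,40.363,5.275,6.608,5.165,788.149,823.593,809.202,-18.4287
36,309.838,41.516,5.425,6.802,5.316,810.635,847.024,832.618,-18.9590
37,318.350,42.669,5.576,7.191,5.620,833.121,870.410,856.497,-19.4844
38,326.874,43.822,5.727,7.385,5.772,855.667,894.049,879.546,-20.0129
39,335.361,44.974,5.877,7.579,5.924,878.154,917.451,903.378,-20.5439
40,343.794,46.127,6.028,7.774,6.076,900.680,941.037,927.399,-21.0765
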