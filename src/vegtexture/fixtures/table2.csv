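Age,Hgt,S_T,S_U,Dn_T,Dn_U,BA_T,BA_U,CC_T,CC_U,H_T,H_U,D_T,D_U
2,2.4,7,3,1850,40,1.023,0.808,4996.664,2954.275,1.325,0.518,0.394,0.728
3,2.7,5,4,4850,102,1.756,1.092,13929.704,7424.604,0.538,0.424,0.756,0.815
5,4.6,4,2,4750,66,6.526,3.887,18587.796,10168.898,0.571,0.136,0.734,0.940
7,4.7,6,1,1825,18,6.150,3.438,18949.464,9832.621,1.293,0,0.367,1
9,4.6,19,7,6775,91,11.068,6.341,31597.844,16515.046,1.975,0.954,0.245,0.539
12,6.1,15,5,4100,46,10.201,6.590,28930.809,14945.067,1.835,1.240,0.281,0.325
13,6.6,29,14,6475,82,15.344,10.523,32446.110,16544.336,2.561,1.851,0.139,0.264
18,7.3,17,10,6925,73,14.604,10.672,31694.175,15909.057,1.730,1.469,0.311,0.391
20,7.0,22,8,4425,58,14.234,8.744,29682.050,15220.037,2.250,1.387,0.220,0.358
25,6.4,12,5,3850,45,11.042,7.022,23283.665,12097.390,1.591,0.814,0.323,0.611
32,6.5,21,9,5600,70,15.464,10.401,33259.234,16699.067,2.299,1.404,0.162,0.372
38,6.5,41,28,7725,122,26.040,17.116,36110.813,18559.764,3.055,2.615,0.070,0.120
42,6.8,27,12,5550,99,21.611,11.820,32099.665,16774.770,2.720,1.640,0.093,0.278
60,8.3,36,11,4500,46,21.441,14.374,36176.727,18135.708,2.993,1.614,0.085,0.330
M,7.0,36,17,7675,57,29.641,15.329,42411.829,21630.317,3.019,2.314,0.071,0.147
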