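attribute,k,r2_T,r2_U
BA,1,0.802,0.784
BA,2,0.926,0.916
BA,3,0.958,0.957
CC,1,0.809,0.802
CC,2,0.885,0.884
CC,3,0.923,0.931
S,1,0.743,0.597
S,2,0.869,0.877
S,3,0.897,0.910
H,1,0.674,0.603
H,2,0.751,0.820
H,3,0.810,0.881
D,1,0.721,0.573
D,2,0.813,0.774
D,3,0.849,0.843
Dn,1,0.354,0.513
Dn,2,0.652,0.685
Dn,3,0.750,0.778
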