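hu,density_g_cm3
-1050,0.00121
-950,0.102
-120,0.950
-82,0.988
-52,1.007
-22,1.027
8,1.043
19,1.052
80,1.089
120,1.145
200,1.192
300,1.251
400,1.310
500,1.369
600,1.428
700,1.487
800,1.546
900,1.605
1000,1.664
1100,1.723
1200,1.782
1300,1.841
1400,1.900
1500,1.959
1640,4.506
2923,8.960
3095,10.490
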