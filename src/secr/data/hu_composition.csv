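hu,H,C,N,O,Na,Mg,P,S,Cl,Ar,K,Ca,Ti,Cu,Zn,Ag,Sn
-1050,0,0,75.5,23.2,0,0,0,0,0,1.3,0,0,0,0,0,0,0
-950,10.3,10.5,3.1,74.9,0.2,0,0.2,0.3,0.3,0,0.2,0,0,0,0,0,0
-120,11.6,68.1,0.2,19.8,0.1,0,0,0.1,0.1,0,0,0,0,0,0,0,0
-82,11.3,56.7,0.9,30.8,0.1,0,0,0.1,0.1,0,0,0,0,0,0,0,0
-52,11.0,45.8,1.5,41.1,0.1,0,0.1,0.2,0.2,0,0,0,0,0,0,0,0
-22,10.8,35.6,2.2,50.9,0,0,0.1,0.2,0.2,0,0,0,0,0,0,0,0
8,10.6,28.4,2.6,57.8,0,0,0.1,0.2,0.2,0,0.1,0,0,0,0,0,0
19,10.3,13.4,3.0,72.3,0.2,0,0.2,0.2,0.2,0,0.2,0,0,0,0,0,0
80,9.4,20.7,6.2,62.2,0.6,0,0,0.6,0.3,0,0,0,0,0,0,0,0
120,9.5,45.5,2.5,35.5,0.1,0,2.1,0.1,0.1,0,0.1,4.5,0,0,0,0,0
200,8.9,42.3,2.7,36.3,0.1,0,3.0,0.1,0.1,0,0.1,6.4,0,0,0,0,0
300,8.2,39.1,2.9,37.2,0.1,0,3.9,0.1,0.1,0,0.1,8.3,0,0,0,0,0
400,7.6,36.1,3.0,38.0,0.1,0.1,4.7,0.2,0.1,0,0,10.1,0,0,0,0,0
500,7.1,33.5,3.2,38.7,0.1,0.1,5.4,0.2,0,0,0,11.7,0,0,0,0,0
600,6.6,31.0,3.3,39.4,0.1,0.1,6.1,0.2,0,0,0,13.2,0,0,0,0,0
700,6.1,28.7,3.5,40.0,0.1,0.1,6.7,0.2,0,0,0,14.6,0,0,0,0,0
800,5.6,26.5,3.6,40.5,0.1,0.2,7.3,0.3,0,0,0,15.9,0,0,0,0,0
900,5.2,24.6,3.7,41.1,0.1,0.2,7.8,0.3,0,0,0,17.0,0,0,0,0,0
1000,4.9,22.7,3.8,41.6,0.1,0.2,8.3,0.3,0,0,0,18.1,0,0,0,0,0
1100,4.5,21.0,3.9,42.0,0.1,0.2,8.8,0.3,0,0,0,19.2,0,0,0,0,0
1200,4.2,19.4,4.0,42.5,0.1,0.2,9.2,0.3,0,0,0,20.1,0,0,0,0,0
1300,3.9,17.9,4.1,42.9,0.1,0.2,9.6,0.3,0,0,0,21.0,0,0,0,0,0
1400,3.6,16.5,4.2,43.2,0.1,0.2,10.0,0.3,0,0,0,21.9,0,0,0,0,0
1500,3.4,15.5,4.2,43.5,0.1,0.2,10.3,0.3,0,0,0,22.5,0,0,0,0,0
1640,0,0,0,0,0,0,0,0,0,0,0,0,100,0,0,0,0
2923,0,0,0,0,0,0,0,0,0,0,0,0,0,100,0,0,0
3095,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,100,0
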