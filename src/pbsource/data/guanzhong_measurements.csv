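sample_no,sample_code,concentration_ppm,204Pb/206Pb,206Pb/207Pb,207Pb/208Pb
1,E-500,54.1385,38.1028,15.6049,18.0156
2,E-1000,12.5050,37.8594,15.5957,17.8272
3,E-1500,35.7557,38.4434,15.6235,18.2839
4,E-2000,28.9605,38.6875,15.6457,18.4706
5,S-500,74.8001,37.8726,15.5961,17.8205
6,S-1000,57.0508,38.0360,15.6040,17.9401
7,S-1500,62.8752,38.0099,15.6020,17.9315
8,S-2000,53.6685,38.1233,15.6042,17.9315
9,W-500,40.6196,38.3144,15.6203,18.1589
10,W-1000,27.6219,38.5274,15.6264,18.1589
11,W-1500,33.7938,38.3724,15.6190,18.1767
12,W-2000,33.8142,38.4927,15.6209,18.2541
13,N-500,60.8520,38.1632,15.6136,18.0387
14,N-1000,27.3358,38.8615,15.6602,18.6236
15,N-1500,22.7273,38.8688,15.6584,18.6297
16,N-2000,24.4338,38.7576,15.6494,18.5355
17,ES-500,53.5663,38.2012,15.6177,18.0890
18,ES-1000,67.9129,38.0017,15.6018,17.9344
19,ES-1500,70.3960,38.0829,15.6054,17.9882
20,ES-2000,61.9352,38.0460,15.6080,17.9504
21,WS-500,44.0939,38.1154,15.6082,17.9999
22,WS-1000,22.993,38.7554,15.6505,18.5365
23,WS-1500,29.5736,38.6739,15.6443,18.4453
24,WS-2000,28.9912,38.6391,15.6394,18.4188
25,WN-500,68.5056,38.0100,15.6040,17.9505
26,WN-1000,40.8751,38.3003,15.6220,18.1678
27,WN-1500,37.7910,38.33,15.6104,18.1393
28,WN-2000,42.9699,38.2237,15.6144,18.1197
29,EN-500,26.7227,38.5385,15.6360,18.3591
30,EN-1000,29.6656,38.5777,15.6369,18.4033
31,EN-1500,29.4612,38.5998,15.6326,18.4123
32,EN-2000,24.7301,38.6627,15.6300,18.3950
33,raw coal of coking plant,184,37.2731,15.5878,17.0701
34,ore of lead and zinc smelter,27.674,38.6392,15.9509,18.4006
35,raw coal of power plant,,38.9844,15.3821,18.3133
36,background value,,37.8781,15.2643,18.8265
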