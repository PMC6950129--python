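sample_no,sample_code,f_coking_pct,f_ore_pct,f_power_pct,f_background_pct
1,E-500,36.18,43.52,3.69,16.61
2,E-1000,49.90,23.94,5.99,20.16
3,E-1500,15.61,40.98,24.89,18.52
4,E-2000,1.86,49.57,31.39,17.18
5,S-500,49.92,23.75,7.38,18.95
6,S-1000,40.60,28.33,13.14,17.92
7,S-1500,41.59,27.81,11.76,18.84
8,S-2000,39.00,27.79,20.69,12.52
9,W-500,24.24,36.99,21.65,17.12
10,W-1000,19.50,37.25,37.96,5.29
11,W-1500,22.10,37.13,25.56,15.22
12,W-2000,15.85,39.44,30.82,13.89
13,N-500,33.18,32.62,16.82,17.38
14,N-1000,-13.86,57.25,41.24,15.37
15,N-1500,-9.20,55.88,35.60,17.71
16,N-2000,-2.59,51.92,33.01,17.66
17,ES-500,57.00,12.18,26.97,3.86
18,ES-1000,41.64,27.90,10.96,19.50
19,ES-1500,37.29,29.93,14.17,18.61
20,ES-2000,39.93,29.30,12.84,17.93
21,WS-500,36.03,30.66,15.79,17.53
22,WS-1000,43.28,31.35,9.67,15.70
23,WS-1500,3.30,48.60,31.85,16.25
24,WS-2000,5.23,47.10,31.16,16.51
25,WN-500,40.72,28.75,10.46,20.07
26,WN-1000,24.16,37.60,19.80,18.43
27,WN-1500,24.70,34.67,25.35,15.28
28,WN-2000,28.05,35.09,17.25,19.60
29,EN-500,10.16,45.05,26.77,18.02
30,EN-1000,7.28,46.43,27.42,18.87
31,EN-1500,5.71,44.72,35.62,13.95
32,EN-2000,5.71,44.72,35.62,13.95
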