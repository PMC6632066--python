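run,filling_level,rotational_speed,blending_time,drug_content,cu,carr_index
1,70,15,16.5,96.77,6.90,19.63
2,70,20,9,92.86,6.19,18.03
3,50,25,9,92.21,9.01,18.50
4,30,20,24,95.70,2.58,18.54
5,50,25,24,94.56,1.67,19.00
6,70,20,24,94.41,7.13,18.52
7,70,25,16.5,90.04,5.18,18.14
8,50,15,9,94.70,2.26,18.84
9,50,15,24,95.36,7.45,18.92
10,50,20,16.5,94.13,5.08,18.40
11,30,25,16.5,95.62,4.18,18.00
12,50,20,16.5,94.42,5.14,18.03
13,30,20,9,93.86,6.15,19.01
14,50,20,16.5,94.13,5.05,19.58
15,30,15,16.5,92.87,4.02,17.94
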