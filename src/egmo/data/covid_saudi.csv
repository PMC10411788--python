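confirmed,recovered,deaths
1720,264,16
1885,328,21
2039,351,25
2179,420,29
2402,488,34
2605,551,38
2795,615,41
2932,631,41
3287,666,44
3651,685,47
4033,720,52
4462,761,59
4934,805,65
5369,889,73
5862,931,79
6380,990,83
7142,1049,87
8274,1329,92
9362,1398,97
10484,1490,103
11631,1640,109
12772,1812,114
13930,1925,121
15102,2049,127
16299,2215,136
17522,2357,139
18811,2531,144
20077,2784,152
21402,2953,157
22753,3163,162
24097,3555,169
25459,3765,176
27011,4134,184
28656,4476,191
30251,5431,200
31938,6783,209
33731,7798,219
35432,9120,229
37136,10144,239
39048,11457,246
41014,12737,255
42925,15257,264
44830,17622,273
46869,19051,283
49176,21869,292
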