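strength
0.101
0.332
0.403
0.428
0.457
0.550
0.561
0.596
0.597
0.645
0.654
0.674
0.718
0.722
0.725
0.732
0.775
0.814
0.816
0.818
0.824
0.859
0.875
0.938
0.940
1.056
1.117
1.128
1.137
1.137
1.177
1.196
1.230
1.325
1.339
1.345
1.420
1.423
1.435
1.443
1.464
1.472
1.494
1.532
1.546
1.577
1.608
1.635
1.693
1.701
1.737
1.754
1.762
1.828
2.052
2.071
2.086
2.171
2.224
2.227
2.425
2.595
3.220
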