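strength
0.312
0.314
0.479
0.552
0.700
0.803
0.861
0.865
0.944
0.958
0.966
0.997
1.006
1.021
1.027
1.055
1.063
1.098
1.140
1.179
1.224
1.240
1.253
1.270
1.272
1.274
1.301
1.301
1.359
1.382
1.382
1.426
1.434
1.435
1.478
1.490
1.511
1.514
1.535
1.554
1.566
1.570
1.586
1.629
1.633
1.642
1.648
1.684
1.697
1.726
1.770
1.773
1.800
1.809
1.818
1.821
1.848
1.880
1.954
2.012
2.067
2.084
2.090
2.096
2.128
2.233
2.433
2.585
2.585
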