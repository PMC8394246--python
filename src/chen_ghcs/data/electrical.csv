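time
0.014
0.034
0.059
0.061
0.069
0.080
0.123
0.142
0.165
0.210
0.381
0.464
0.479
0.556
0.574
0.839
0.917
0.969
0.991
1.064
1.088
1.091
1.174
1.270
1.275
1.355
1.397
1.477
1.578
1.649
1.702
1.893
1.932
2.001
2.161
2.292
2.326
2.337
2.628
2.785
2.811
2.886
2.993
3.122
3.248
3.715
3.790
3.857
3.912
4.100
4.106
4.116
4.315
4.510
4.580
5.267
5.299
5.583
6.065
9.701
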