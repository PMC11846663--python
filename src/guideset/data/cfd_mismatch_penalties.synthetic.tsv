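# Synthetic mismatch-penalty table (stand-in; not published measurements).
# penalty = position_profile(position) * pair_weight(rna_base, dna_base)
position	rna_base	dna_base	penalty
1	A	C	0.5000
1	A	G	0.7000
1	A	T	0.4000
1	C	A	0.6500
1	C	G	0.5500
1	C	T	0.4500
1	G	A	1.0000
1	G	C	0.4500
1	G	T	0.3500
1	U	A	0.6000
1	U	C	0.9500
1	U	G	0.5000
2	A	C	0.4619
2	A	G	0.6466
2	A	T	0.3695
2	C	A	0.6004
2	C	G	0.5081
2	C	T	0.4157
2	G	A	0.9238
2	G	C	0.4157
2	G	T	0.3233
2	U	A	0.5543
2	U	C	0.8776
2	U	G	0.4619
3	A	C	0.4250
3	A	G	0.5950
3	A	T	0.3400
3	C	A	0.5525
3	C	G	0.4675
3	C	T	0.3825
3	G	A	0.8500
3	G	C	0.3825
3	G	T	0.2975
3	U	A	0.5100
3	U	C	0.8075
3	U	G	0.4250
4	A	C	0.3894
4	A	G	0.5452
4	A	T	0.3115
4	C	A	0.5062
4	C	G	0.4284
4	C	T	0.3505
4	G	A	0.7788
4	G	C	0.3505
4	G	T	0.2726
4	U	A	0.4673
4	U	C	0.7399
4	U	G	0.3894
5	A	C	0.3551
5	A	G	0.4972
5	A	T	0.2841
5	C	A	0.4617
5	C	G	0.3906
5	C	T	0.3196
5	G	A	0.7103
5	G	C	0.3196
5	G	T	0.2486
5	U	A	0.4262
5	U	C	0.6748
5	U	G	0.3551
6	A	C	0.3222
6	A	G	0.4511
6	A	T	0.2578
6	C	A	0.4189
6	C	G	0.3544
6	C	T	0.2900
6	G	A	0.6444
6	G	C	0.2900
6	G	T	0.2255
6	U	A	0.3866
6	U	C	0.6122
6	U	G	0.3222
7	A	C	0.2906
7	A	G	0.4069
7	A	T	0.2325
7	C	A	0.3778
7	C	G	0.3197
7	C	T	0.2616
7	G	A	0.5813
7	G	C	0.2616
7	G	T	0.2035
7	U	A	0.3488
7	U	C	0.5522
7	U	G	0.2906
8	A	C	0.2605
8	A	G	0.3647
8	A	T	0.2084
8	C	A	0.3387
8	C	G	0.2866
8	C	T	0.2345
8	G	A	0.5210
8	G	C	0.2345
8	G	T	0.1824
8	U	A	0.3126
8	U	C	0.4950
8	U	G	0.2605
9	A	C	0.2319
9	A	G	0.3246
9	A	T	0.1855
9	C	A	0.3014
9	C	G	0.2550
9	C	T	0.2087
9	G	A	0.4637
9	G	C	0.2087
9	G	T	0.1623
9	U	A	0.2782
9	U	C	0.4405
9	U	G	0.2319
10	A	C	0.2047
10	A	G	0.2866
10	A	T	0.1638
10	C	A	0.2661
10	C	G	0.2252
10	C	T	0.1842
10	G	A	0.4094
10	G	C	0.1842
10	G	T	0.1433
10	U	A	0.2457
10	U	C	0.3890
10	U	G	0.2047
11	A	C	0.1792
11	A	G	0.2508
11	A	T	0.1433
11	C	A	0.2329
11	C	G	0.1971
11	C	T	0.1613
11	G	A	0.3583
11	G	C	0.1613
11	G	T	0.1254
11	U	A	0.2150
11	U	C	0.3404
11	U	G	0.1792
12	A	C	0.1553
12	A	G	0.2174
12	A	T	0.1242
12	C	A	0.2018
12	C	G	0.1708
12	C	T	0.1397
12	G	A	0.3105
12	G	C	0.1397
12	G	T	0.1087
12	U	A	0.1863
12	U	C	0.2950
12	U	G	0.1553
13	A	C	0.1331
13	A	G	0.1863
13	A	T	0.1065
13	C	A	0.1730
13	C	G	0.1464
13	C	T	0.1198
13	G	A	0.2662
13	G	C	0.1198
13	G	T	0.0932
13	U	A	0.1597
13	U	C	0.2529
13	U	G	0.1331
14	A	C	0.1127
14	A	G	0.1578
14	A	T	0.0902
14	C	A	0.1466
14	C	G	0.1240
14	C	T	0.1015
14	G	A	0.2255
14	G	C	0.1015
14	G	T	0.0789
14	U	A	0.1353
14	U	C	0.2142
14	U	G	0.1127
15	A	C	0.0943
15	A	G	0.1321
15	A	T	0.0755
15	C	A	0.1226
15	C	G	0.1038
15	C	T	0.0849
15	G	A	0.1887
15	G	C	0.0849
15	G	T	0.0660
15	U	A	0.1132
15	U	C	0.1792
15	U	G	0.0943
16	A	C	0.0780
16	A	G	0.1092
16	A	T	0.0624
16	C	A	0.1014
16	C	G	0.0858
16	C	T	0.0702
16	G	A	0.1560
16	G	C	0.0702
16	G	T	0.0546
16	U	A	0.0936
16	U	C	0.1482
16	U	G	0.0780
17	A	C	0.0640
17	A	G	0.0896
17	A	T	0.0512
17	C	A	0.0832
17	C	G	0.0704
17	C	T	0.0576
17	G	A	0.1280
17	G	C	0.0576
17	G	T	0.0448
17	U	A	0.0768
17	U	C	0.1216
17	U	G	0.0640
18	A	C	0.0525
18	A	G	0.0736
18	A	T	0.0420
18	C	A	0.0683
18	C	G	0.0578
18	C	T	0.0473
18	G	A	0.1051
18	G	C	0.0473
18	G	T	0.0368
18	U	A	0.0631
18	U	C	0.0998
18	U	G	0.0525
19	A	C	0.0441
19	A	G	0.0618
19	A	T	0.0353
19	C	A	0.0574
19	C	G	0.0486
19	C	T	0.0397
19	G	A	0.0883
19	G	C	0.0397
19	G	T	0.0309
19	U	A	0.0530
19	U	C	0.0839
19	U	G	0.0441
20	A	C	0.0400
20	A	G	0.0560
20	A	T	0.0320
20	C	A	0.0520
20	C	G	0.0440
20	C	T	0.0360
20	G	A	0.0800
20	G	C	0.0360
20	G	T	0.0280
20	U	A	0.0480
20	U	C	0.0760
20	U	G	0.0400
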