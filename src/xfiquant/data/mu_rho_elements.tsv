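# Elemental photon mass attenuation coefficients (total, with coherent)
# element	energy_keV	mu_over_rho_cm2_g
H	5	0.4193
H	6	0.4042
H	8	0.3914
H	10	0.3854
H	15	0.3764
H	20	0.3695
H	30	0.357
H	40	0.3458
H	50	0.3355
H	60	0.326
H	80	0.3091
H	100	0.2944
Be	5	4.1696
Be	6	2.456
Be	8	1.1158
Be	10	0.6466
Be	15	0.30496
Be	20	0.22177
Be	30	0.17598
Be	40	0.16143
Be	50	0.15349
Be	60	0.14778
Be	80	0.13909
Be	100	0.13211
C	5	18.509
C	6	10.658
C	8	4.5198
C	10	2.373
C	15	0.81707
C	20	0.44552
C	30	0.25448
C	40	0.20501
C	50	0.18451
C	60	0.17305
C	80	0.15932
C	100	0.15009
N	5	31.156
N	6	17.884
N	8	7.5075
N	10	3.879
N	15	1.2509
N	20	0.62492
N	30	0.30621
N	40	0.22644
N	50	0.19534
N	60	0.17926
N	80	0.16192
N	100	0.15143
O	5	48.563
O	6	27.83
O	8	11.62
O	10	5.952
O	15	1.848
O	20	0.87186
O	30	0.3774
O	40	0.25593
O	50	0.21025
O	60	0.18782
O	80	0.16551
O	100	0.15328
Na	5	127.13
Na	6	72.715
Na	8	30.173
Na	10	15.3
Na	15	4.5345
Na	20	1.978
Na	30	0.69052
Na	40	0.38109
Na	50	0.26983
Na	60	0.21895
Na	80	0.17459
Na	100	0.15485
Mg	5	173.27
Mg	6	99.083
Mg	8	41.079
Mg	10	20.8
Mg	15	6.1226
Mg	20	2.6379
Mg	30	0.88443
Mg	40	0.46431
Mg	50	0.31426
Mg	60	0.2464
Mg	80	0.18862
Mg	100	0.16405
Si	5	283.27
Si	6	161.93
Si	8	67.066
Si	10	33.9
Si	15	9.8967
Si	20	4.1994
Si	30	1.3354
Si	40	0.6517
Si	50	0.40949
Si	60	0.30145
Si	80	0.21222
Si	100	0.17661
P	5	335.37
P	6	191.7
P	8	79.371
P	10	40.1
P	15	11.679
P	20	4.9331
P	30	1.5431
P	40	0.73475
P	50	0.44904
P	60	0.32213
P	80	0.21828
P	100	0.17768
S	5	420.99
S	6	240.62
S	8	99.601
S	10	50.3
S	15	14.62
S	20	6.1525
S	30	1.898
S	40	0.88445
S	50	0.52691
S	60	0.36862
S	80	0.2401
S	100	0.19074
Cl	5	483.19
Cl	6	276.16
Cl	8	114.29
Cl	10	57.7
Cl	15	16.746
Cl	20	7.0273
Cl	30	2.145
Cl	40	0.98269
Cl	50	0.57326
Cl	60	0.39246
Cl	80	0.24652
Cl	100	0.19126
Ar	5	525.26
Ar	6	300.19
Ar	8	124.22
Ar	10	62.7
Ar	15	18.178
Ar	20	7.6133
Ar	30	2.3065
Ar	40	1.0437
Ar	50	0.59928
Ar	60	0.40341
Ar	80	0.24596
Ar	100	0.18693
K	5	662.88
K	6	378.83
K	8	156.74
K	10	79.1
K	15	22.911
K	20	9.5777
K	30	2.8812
K	40	1.2883
K	50	0.72837
K	60	0.48195
K	80	0.28465
K	100	0.21137
Ca	5	804.77
Ca	6	459.9
Ca	8	190.26
Ca	10	96
Ca	15	27.782
Ca	20	11.594
Ca	30	3.4653
Ca	40	1.5325
Ca	50	0.85354
Ca	60	0.55524
Ca	80	0.31725
Ca	100	0.22963
Fe	5	1431.3
Fe	6	817.89
Fe	8	338.27
Fe	10	170.6
Fe	15	49.258
Fe	20	20.467
Fe	30	6.0122
Fe	40	2.5788
Fe	50	1.3755
Fe	60	0.84896
Fe	80	0.43282
Fe	100	0.28321
Zn	5	1863
Zn	6	1064.5
Zn	8	440.25
Zn	10	222
Zn	15	64.06
Zn	20	26.585
Zn	30	7.7726
Zn	40	3.3054
Zn	50	1.7407
Zn	60	1.0567
Zn	80	0.51752
Zn	100	0.32496
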