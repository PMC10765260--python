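# Synthetic background-mortality life table: United States 2018, female, all-cause.
# NOT a verbatim transcription of the published table: annual hazards are a monotone
# PCHIP interpolation of log-hazard through approximate published anchor values,
# log-linearly extrapolated beyond age 100.
# Anchors (age: annual death probability): 30: 0.00075, 40: 0.00135, 50: 0.00315, 60: 0.0072, 70: 0.0164, 80: 0.044, 90: 0.138, 100: 0.358
# Ages 0-29 are hand-set knots with log-linear interpolation (unused by the model,
# which starts cohorts at age >= 42).
age,annual_death_prob
0,0.00520000
1,0.00035000
2,0.00026206
3,0.00019621
4,0.00014691
5,0.00011000
6,0.00011193
7,0.00011390
8,0.00011590
9,0.00011793
10,0.00012000
11,0.00014216
12,0.00016841
13,0.00019951
14,0.00023635
15,0.00028000
16,0.00030070
17,0.00032294
18,0.00034682
19,0.00037246
20,0.00040000
21,0.00041826
22,0.00043734
23,0.00045731
24,0.00047818
25,0.00050000
26,0.00054224
27,0.00058804
28,0.00063771
29,0.00069158
30,0.00075000
31,0.00078633
32,0.00082683
33,0.00087184
34,0.00092175
35,0.00097695
36,0.00103790
37,0.00110512
38,0.00117913
39,0.00126054
40,0.00135000
41,0.00145139
42,0.00156876
43,0.00170306
44,0.00185514
45,0.00202566
46,0.00221503
47,0.00242317
48,0.00264947
49,0.00289252
50,0.00315000
51,0.00342438
52,0.00372142
53,0.00404310
54,0.00439160
55,0.00476932
56,0.00517893
57,0.00562337
58,0.00610588
59,0.00663009
60,0.00720000
61,0.00781376
62,0.00847023
63,0.00917575
64,0.00993810
65,0.01076673
66,0.01167308
67,0.01267101
68,0.01377724
69,0.01501204
70,0.01640000
71,0.01795961
72,0.01970486
73,0.02165960
74,0.02385084
75,0.02630925
76,0.02906958
77,0.03217122
78,0.03565877
79,0.03958269
80,0.04400000
81,0.04905446
82,0.05490195
83,0.06162380
84,0.06929925
85,0.07800029
86,0.08778529
87,0.09869130
88,0.11072537
89,0.12385521
90,0.13800000
91,0.15321117
92,0.16967499
93,0.18747654
94,0.20670794
95,0.22746822
96,0.24986266
97,0.27400139
98,0.29999714
99,0.32796156
100,0.35800000
101,0.39004451
102,0.42390769
103,0.45946978
104,0.49655651
105,0.53493364
106,0.57430309
107,0.61430165
108,0.65450325
109,0.69442555
110,0.73354194
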