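age,qx
0,0.00053
1,0.00053283
2,0.00053592
3,0.0005393
4,0.000543
5,0.00054705
6,0.00055148
7,0.00055633
8,0.00056163
9,0.00056744
10,0.00057379
11,0.00058074
12,0.00058834
13,0.00059666
14,0.00060576
15,0.00061572
16,0.00062662
17,0.00063855
18,0.00065159
19,0.00066587
20,0.00068149
21,0.00069858
22,0.00071728
23,0.00073774
24,0.00076013
25,0.00078463
26,0.00081144
27,0.00084077
28,0.00087286
29,0.00090797
30,0.00094639
31,0.00098843
32,0.00103443
33,0.00108476
34,0.00113983
35,0.00120008
36,0.00126601
37,0.00133815
38,0.00141708
39,0.00150345
40,0.00159795
41,0.00170135
42,0.00181448
43,0.00193827
44,0.00207372
45,0.00222192
46,0.00238408
47,0.00256152
48,0.00275566
49,0.00296808
50,0.00320051
51,0.00345483
52,0.0037331
53,0.00403758
54,0.00437073
55,0.00473525
56,0.0051341
57,0.00557051
58,0.00604803
59,0.00657051
60,0.00714219
61,0.00776772
62,0.00845215
63,0.00920104
64,0.01002045
65,0.01091703
66,0.01189805
67,0.01297145
68,0.01414594
69,0.01543104
70,0.01683716
71,0.0183757
72,0.02005913
73,0.0219011
74,0.02391653
75,0.02612176
76,0.02853467
77,0.03117482
78,0.0340636
79,0.03722443
80,0.04068292
81,0.04446712
82,0.04860769
83,0.0531382
84,0.05809537
85,0.06351937
86,0.06945417
87,0.07594788
88,0.08305313
89,0.09082751
90,0.09933404
91,0.10864167
92,0.11882583
93,0.12996908
94,0.14216174
95,0.15550263
96,0.17009989
97,0.18607184
98,0.20354794
99,0.22266983
100,1.0
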