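age,qx_female,qx_male
0,0.005000,0.006000
1,0.000272,0.000437
2,0.000274,0.000441
3,0.000277,0.000445
4,0.000280,0.000450
5,0.000283,0.000455
6,0.000286,0.000460
7,0.000290,0.000466
8,0.000294,0.000473
9,0.000298,0.000480
10,0.000303,0.000488
11,0.000308,0.000497
12,0.000314,0.000506
13,0.000321,0.000517
14,0.000328,0.000529
15,0.000336,0.000541
16,0.000345,0.000555
17,0.000355,0.000571
18,0.000366,0.000588
19,0.000378,0.000607
20,0.000391,0.000627
21,0.000405,0.000650
22,0.000421,0.000675
23,0.000438,0.000702
24,0.000458,0.000732
25,0.000479,0.000766
26,0.000502,0.000802
27,0.000528,0.000842
28,0.000557,0.000886
29,0.000588,0.000935
30,0.000623,0.000988
31,0.000661,0.001046
32,0.000703,0.001111
33,0.000749,0.001182
34,0.000800,0.001260
35,0.000857,0.001345
36,0.000919,0.001439
37,0.000987,0.001543
38,0.001063,0.001657
39,0.001146,0.001782
40,0.001238,0.001920
41,0.001339,0.002071
42,0.001451,0.002238
43,0.001574,0.002421
44,0.001709,0.002622
45,0.001859,0.002844
46,0.002024,0.003087
47,0.002205,0.003355
48,0.002405,0.003650
49,0.002626,0.003974
50,0.002869,0.004330
51,0.003138,0.004722
52,0.003433,0.005152
53,0.003760,0.005626
54,0.004119,0.006147
55,0.004515,0.006719
56,0.004952,0.007349
57,0.005433,0.008042
58,0.005964,0.008803
59,0.006550,0.009641
60,0.007195,0.010561
61,0.007906,0.011574
62,0.008690,0.012688
63,0.009554,0.013912
64,0.010507,0.015259
65,0.011558,0.016740
66,0.012716,0.018368
67,0.013992,0.020159
68,0.015400,0.022128
69,0.016951,0.024293
70,0.018662,0.026675
71,0.020547,0.029293
72,0.022626,0.032173
73,0.024917,0.035339
74,0.027443,0.038821
75,0.030228,0.042650
76,0.033299,0.046861
77,0.036683,0.051491
78,0.040414,0.056582
79,0.044528,0.062182
80,0.049062,0.068339
81,0.054061,0.075109
82,0.059572,0.082555
83,0.065647,0.090742
84,0.072344,0.099746
85,0.079728,0.109646
86,0.087867,0.120534
87,0.096840,0.132506
88,0.106732,0.145672
89,0.117637,0.160149
90,0.129659,0.176070
91,0.142912,0.193577
92,0.157522,0.212828
93,0.173628,0.233999
94,0.191384,0.257279
95,0.210959,0.282879
96,0.232538,0.311031
97,0.256327,0.341988
98,0.282552,0.376030
99,0.311463,0.413465
100,1.000000,1.000000
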