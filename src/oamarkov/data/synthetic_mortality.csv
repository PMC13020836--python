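age,q
45,0.001113
46,0.001233
47,0.001365
48,0.001511
49,0.001674
50,0.001853
51,0.002052
52,0.002273
53,0.002517
54,0.002787
55,0.003087
56,0.003418
57,0.003785
58,0.004191
59,0.004642
60,0.005140
61,0.005692
62,0.006303
63,0.006980
64,0.007730
65,0.008560
66,0.009479
67,0.010497
68,0.011624
69,0.012872
70,0.014254
71,0.015785
72,0.017480
73,0.019357
74,0.021435
75,0.023737
76,0.026286
77,0.029109
78,0.032235
79,0.035696
80,0.039530
81,0.043774
82,0.048475
83,0.053680
84,0.059445
85,0.065828
86,0.072897
87,0.080725
88,0.089393
89,0.098993
90,0.109623
91,0.121395
92,0.134431
93,0.148866
94,0.164852
95,0.182554
96,0.202158
97,0.223866
98,0.247905
99,0.274526
100,0.304006
101,0.336651
102,0.372802
103,0.412835
104,0.457166
105,0.506259
106,0.560622
107,0.620824
108,0.687490
109,0.761315
110,0.843068
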