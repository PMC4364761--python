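# Synthetic approximation of the US 2011 all-cause period life table (qx).
# Geometric interpolation of quinquennial anchors of NVSS-reported magnitude.
age	qx
45	0.002990
46	0.003205
47	0.003435
48	0.003682
49	0.003946
50	0.004230
51	0.004551
52	0.004897
53	0.005269
54	0.005669
55	0.006100
56	0.006624
57	0.007193
58	0.007811
59	0.008482
60	0.009210
61	0.009923
62	0.010691
63	0.011518
64	0.012410
65	0.013370
66	0.014589
67	0.015918
68	0.017369
69	0.018953
70	0.020680
71	0.022504
72	0.024490
73	0.026650
74	0.029001
75	0.031560
76	0.034859
77	0.038502
78	0.042526
79	0.046971
80	0.051880
81	0.057488
82	0.063701
83	0.070586
84	0.078216
85	0.086670
86	0.095760
87	0.105804
88	0.116902
89	0.129163
90	0.142710
91	0.156509
92	0.171642
93	0.188238
94	0.206439
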