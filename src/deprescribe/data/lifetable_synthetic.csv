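age,sex,qx_noncvd
80,M,0.04350
81,M,0.04784
82,M,0.05260
83,M,0.05784
84,M,0.06361
85,M,0.06995
86,M,0.07692
87,M,0.08459
88,M,0.09302
89,M,0.10228
90,M,0.11248
91,M,0.12369
92,M,0.13601
93,M,0.14957
94,M,0.16448
95,M,0.18087
96,M,0.19889
97,M,0.21871
98,M,0.24051
99,M,0.26448
100,M,0.29084
101,M,0.31982
102,M,0.35169
103,M,0.38674
104,M,0.42529
105,M,0.46767
106,M,0.51428
107,M,0.56553
108,M,0.62189
109,M,0.68387
110,M,0.70000
80,F,0.03450
81,F,0.03813
82,F,0.04214
83,F,0.04657
84,F,0.05147
85,F,0.05688
86,F,0.06286
87,F,0.06947
88,F,0.07678
89,F,0.08486
90,F,0.09378
91,F,0.10364
92,F,0.11454
93,F,0.12659
94,F,0.13990
95,F,0.15462
96,F,0.17088
97,F,0.18885
98,F,0.20871
99,F,0.23066
100,F,0.25492
101,F,0.28173
102,F,0.31136
103,F,0.34411
104,F,0.38030
105,F,0.42030
106,F,0.46450
107,F,0.51335
108,F,0.56734
109,F,0.62701
110,F,0.69295
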