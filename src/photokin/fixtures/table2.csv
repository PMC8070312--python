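time_min,x0.0,x0.1,x0.2,x0.3,x0.4,x0.5
0,1.0000,1.0000,1.0000,1.0000,1.0000,1.0000
10,0.95262,0.93157,0.91825,0.87202,0.76098,0.63343
20,0.94483,0.90611,0.86885,0.82652,0.66659,0.48658
30,0.93155,0.88672,0.84257,0.81391,0.62154,0.45549
60,0.90482,0.84761,0.77303,0.71679,0.49868,0.35593
90,0.89377,0.82376,0.70142,0.67588,0.48610,0.29267
120,0.87756,0.79047,0.67476,0.61014,0.45405,0.16191
180,0.85318,0.75315,0.62379,0.55294,0.33335,0.11268
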