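x,k1_e3_per_min,correlation_r
0.0,0.92346,0.93616
0.1,1.6555,0.94957
0.2,2.8425,0.96295
0.3,3.4763,0.96232
0.4,6.1409,0.93675
0.5,12.4751,0.96706
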