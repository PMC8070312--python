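x,band_gap_ev
0.0,1.62
0.1,1.67
0.2,1.68
0.3,1.74
0.4,1.84
0.5,1.87
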