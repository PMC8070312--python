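x,surface_area_m2_per_g,pore_volume_cm3_per_g,pore_diameter_angstrom
0.0,138,0.180,58
0.1,101.5,0.190,72
0.2,108,0.210,84
0.3,101,0.196,72
0.4,69,0.150,82
0.5,43,0.086,82
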