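time_min,sqrt_t_min05,x0.0,x0.1,x0.2,x0.3,x0.4,x0.5
0,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000,0.0000
10,3.1623,-0.04854,-0.07088,-0.085286,-0.13694,-0.273,-0.4566
20,4.4721,-0.05675,-0.0985,-0.14059,-0.19053,-0.406,-0.7203
30,5.4772,-0.07091,-0.12023,-0.17130,-0.20591,-0.476,-0.7863
60,7.7460,-0.10002,-0.1653,-0.25744,-0.33297,-0.695,-1.0330
90,9.4868,-0.11231,-0.1938,-0.35465,-0.39174,-0.721,-1.2287
120,10.954,-0.13061,-0.23513,-0.39340,-0.49407,-0.789,-1.8207
180,13.416,-0.15879,-0.28349,-0.47195,-0.59251,-1.098,-2.1832
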