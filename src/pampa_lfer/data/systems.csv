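system_id,name,category,c,e,s,a,b,v,se_c,se_e,se_s,se_a,se_b,se_v,n,sd,r2,f,ref
1,PAMPA-Certramide,pampa,-4.181,0.064,-0.594,-1.038,-2.269,1.730,0.088,0.104,0.049,0.080,0.096,0.079,45,0.154,0.964,210.6,"certramide, cholesterol, stearic acid, and silicone oil"
2,PAMPA-IPM,pampa,-4.202,0.081,-0.500,-0.597,-2.044,1.441,0.195,0.216,0.112,0.234,0.229,0.223,27,0.296,0.835,21.3,"70% silicone oil and 30% IPM"
3,PAMPA-BBB,pampa,,0.250,-1.290,0.250,-2.370,3.030,,,,,,,,,,,"10% (w/v) porcine brain lipid extract in alkane"
4,PAMPA-HDM,pampa,,0.106,-1.440,-3.180,-4.240,4.090,,,,,,,,,,,"n-hexadecane"
5,PAMPA-DOPC,pampa,,0.510,-0.860,-2.570,-4.070,3.990,,,,,,,,,,,"2% w/v dioleyoylphosphatidylcholine in n-dodecane"
6,PAMPA-DS,pampa,,-0.026,-2.170,-0.951,-3.450,5.010,,,,,,,,,,,"20% (w/v) of a lecithin mixture in n-dodecane"
7,PAMPA-P0,pampa,,0.250,-1.840,-1.480,-2.460,4.020,,,,,,,,,,,"20% (w/v) of a lecithin mixture in n-dodecane"
8,PAMPA-COS,pampa,,-0.130,-1.170,-3.650,-2.760,3.330,,,,,,,,,,,"20% (w/v) of a lecithin mixture in n-dodecane"
9,PAMPA-P16,pampa,,0.000,-0.121,-0.188,-0.479,0.194,,,,,,,,,,,"n-hexadecane"
10,Skin permeation,biological,,0.137,-0.604,-0.338,-2.428,1.797,,,,,,,,,,,
11,Skin partition,biological,,0.341,-0.206,-0.024,-2.178,1.850,,,,,,,,,,,
12,HIA,biological,,0.000,0.000,-0.284,-0.343,0.262,,,,,,,,,,,
13,Blood-brain partition,biological,,0.221,-0.604,-0.641,-0.681,0.635,,,,,,,,,,,
14,Saline-brain permeation,biological,,-0.047,-0.876,-0.719,-1.571,1.767,,,,,,,,,,,
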