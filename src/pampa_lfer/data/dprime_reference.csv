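biological_id,1,2,3,4,5,6,7,8
10,0.72,0.60,1.53,4.16,3.56,3.77,2.79,3.72
11,1.13,0.82,1.64,4.56,3.89,4.06,3.10,4.10
12,2.61,2.15,3.71,6.35,5.83,6.11,4.85,5.29
13,1.98,1.59,3.14,5.64,5.16,5.42,4.11,4.59
14,0.83,0.71,1.85,4.35,3.86,3.97,2.73,3.54
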