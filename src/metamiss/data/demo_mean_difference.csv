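mean_c,mean_t,sd_c,sd_t,n_c,n_t
1.02,2.10,0.21,0.45,10,11
0.95,1.80,,,9,12
1.10,2.40,0.30,0.52,8,8
0.88,1.95,0.18,0.40,,
1.25,2.20,0.27,0.61,14,10
0.99,2.05,,,11,9
1.05,1.70,0.22,0.35,13,12
1.15,2.60,0.31,0.70,7,9
0.92,1.88,0.19,0.44,10,10
1.08,2.30,0.24,0.55,12,11
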