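lactate_mM,ca_ss_nM,sem_nM
0.08,50,3.0
0.4,39,6.9
0.8,35,7.8
1.5,24,0.6
10,14,1.1
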