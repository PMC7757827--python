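lactate_mM,ca_ss_nM,sem_nM
0.08,240,39
0.4,183,37
0.8,157,20
1.5,103,9
10,61,5
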