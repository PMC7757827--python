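experiment,p,q,r,d,g,r2
1,9.30e-2,2.13e-8,5.93e-5,2.09e-5,3.40e-3,0.98
2,0.147,6.56e-9,7.56e-5,2.17e-5,3.50e-3,0.99
3,6.70e-2,8.87e-9,1.02e-4,1.17e-5,5.70e-3,0.98
4,0.267,2.03e-8,6.00e-5,2.22e-5,4.00e-3,0.99
5,0.47,2.69e-9,6.52e-5,1.67e-5,2.90e-3,0.98
6,0.166,1.48e-8,6.53e-5,2.73e-5,2.00e-3,0.99
7,0.366,1.98e-9,5.82e-5,2.68e-5,2.90e-3,0.99
8,0.543,2.06e-8,3.96e-5,4.08e-5,3.60e-3,0.97
9,5.93e-2,1.32e-8,6.55e-5,1.50e-5,5.30e-3,0.99
10,0.2596,7.32e-8,4.70e-5,1.18e-5,3.30e-3,0.98
11,6.32e-2,4.34e-8,4.94e-5,3.37e-5,2.00e-3,0.98
12,3.25e-2,3.51e-9,4.56e-5,3.76e-5,2.30e-3,0.98
13,0.435,1.74e-8,5.25e-5,2.32e-5,2.60e-3,0.98
14,0.658,1.66e-8,7.25e-5,1.61e-5,4.70e-3,0.99
15,7.23e-2,5.55e-10,8.34e-5,2.14e-5,2.50e-3,0.98
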