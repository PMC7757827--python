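{
  "geometry": {
    "vol_cyt": 8.6e-13,
    "vol_ret": 1.3e-13,
    "vol_ves": 1.8e-15,
    "a_ret": 3.6e-7,
    "a_ves": 2.1e-9,
    "f_cyt": 0.01,
    "f_ret": 0.01,
    "f_ves": 0.01
  },
  "physical": {
    "p_leak1": 1.0e-7,
    "p_leak2": 1.0e-7,
    "alpha": 1.0,
    "beta": 1.0,
    "k3_prime": 288,
    "k2_atpase_ret": 3.36,
    "k2p_k1p_atpase_ves": 288,
    "km_atp": 0.002
  },
  "characteristic": {
    "ca_cyt_ss_nM": 77,
    "ca_cyt_min_nM": 15,
    "ca_cyt_max_nM": 300,
    "ca_ret_nM": 60000,
    "ca_ves_nM": 40000,
    "atp_mM": 1.33
  }
}
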