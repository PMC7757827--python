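{
  "delta": 0.0013,
  "phi": 0.0110,
  "omega": 1.8251,
  "k_l": 52.4576,
  "b": 3.6864e-6,
  "with_thapsigargin": true
}
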