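{
  "delta": 1.67e-4,
  "phi": 0.3162,
  "omega": 1.4142,
  "k_l": 2,
  "b": 1.2083e-4,
  "with_thapsigargin": true
}
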