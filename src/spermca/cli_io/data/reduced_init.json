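{
  "p": 1.68,
  "q": 5.96e-4,
  "r": 3.93e-4,
  "d": 2.81e-4,
  "g": 2.80e-3
}
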