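{
  "n": 82,
  "n_male": 46,
  "n_female": 36,
  "taad": 33,
  "arterial_any": 38,
  "connective": 76
}
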