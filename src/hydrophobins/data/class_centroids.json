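{
  "class_I": [7.0, 0.0, 22.0, 12.0, 7.0, 0.0, 14.0],
  "class_II": [10.0, 0.0, 11.0, 16.0, 8.0, 0.0, 6.0]
}
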