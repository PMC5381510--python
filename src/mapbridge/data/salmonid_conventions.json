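{
  "comment": "Curated origin constraints for two arm-pair characters whose phylogenetic placement is not determined by the uniform minimal-event rule; see docs/methods.md.",
  "origin_policy": {
    "15.1|4.1": "single",
    "13.2|2.2": "independent"
  }
}
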