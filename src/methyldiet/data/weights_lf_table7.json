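{
  "diet": "LF",
  "weights": {
    "cg15572235": 7.57,
    "cg19424457": -8.04,
    "cg18493115": -6.26,
    "cg00481382": 5.78,
    "cg16600909": 5.38,
    "cg15837280": 5.83,
    "cg03188948": -4.30,
    "cg16078649": -4.16,
    "cg15011943": 4.64,
    "cg07167872": 3.98,
    "cg14222729": -3.40
  }
}
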