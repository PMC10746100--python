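{
  "diet": "LF",
  "weights": {
    "cg15572235": 7.570,
    "cg19424457": -8.048,
    "cg18493115": -6.267,
    "cg00481382": 5.789,
    "cg16600909": 5.380,
    "cg15837280": 5.830,
    "cg03188948": -4.308,
    "cg16078649": -4.163,
    "cg15011943": 4.649,
    "cg07167872": 3.986,
    "cg14222729": -3.407
  }
}
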