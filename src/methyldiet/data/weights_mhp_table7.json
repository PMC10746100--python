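{
  "diet": "MHP",
  "weights": {
    "cg22355889": 9.82,
    "cg24433124": -5.81,
    "cg14317533": -7.58,
    "cg07104639": 6.25,
    "cg19148731": -7.88,
    "cg01097406": -5.98,
    "cg15263617": 8.97,
    "cg23377942": -4.19,
    "cg25340688": -5.79,
    "cg19053046": 5.08,
    "cg11460778": 4.22,
    "cg03447554": -4.08,
    "cg09768983": 3.98,
    "cg20684491": 4.80,
    "cg20315590": -6.71
  }
}
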