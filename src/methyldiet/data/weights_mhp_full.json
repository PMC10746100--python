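{
  "diet": "MHP",
  "weights": {
    "cg22355889": 9.818,
    "cg24433124": -5.813,
    "cg14317533": -7.578,
    "cg07104639": 6.259,
    "cg19148731": -7.880,
    "cg01097406": -5.982,
    "cg15263617": 8.975,
    "cg23377942": -4.191,
    "cg25340688": -5.795,
    "cg19053046": 5.080,
    "cg11460778": 4.222,
    "cg03447554": -4.080,
    "cg09768983": 3.989,
    "cg20684491": 4.803,
    "cg20315590": -6.713
  }
}
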