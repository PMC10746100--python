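{
  "description": "Published fixed-effect coefficients of the %BMIL prediction model: %BMIL ~ diet + total methylation score + diet:score, adjusted for age and sex. SEs printed as '< 0.001' are stored as null. p-values printed as '<0.001' are stored with p_upper_bound true.",
  "n": 201,
  "model_p_value": "<=0.001",
  "coefficients": {
    "age": {"beta": -0.001, "se": null, "p": 0.943, "p_upper_bound": false},
    "sex": {"beta": -0.006, "se": 0.1, "p": 0.954, "p_upper_bound": false},
    "diet": {"beta": -1.201, "se": 0.1, "p": 0.001, "p_upper_bound": true},
    "score": {"beta": 0.202, "se": 0.01, "p": 0.001, "p_upper_bound": true},
    "diet:score": {"beta": -0.208, "se": 0.02, "p": 0.001, "p_upper_bound": true},
    "const": {"beta": -7.952, "se": 0.6, "p": 0.001, "p_upper_bound": true}
  }
}
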