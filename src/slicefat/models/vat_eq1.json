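{
 "loa_lower_cm2": -21.46,
 "loa_upper_cm2": 21.51,
 "n": 68,
 "r_squared": 0.978,
 "residual_sd": 11.5,
 "response": "vat_manual_cm2",
 "terms": {
  "intercept": 7.224,
  "obesity": 7.583,
  "vat_otsu_cm2": 1.112
 },
 "weighting": "inverse_sex_age_frequency"
}
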