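{
 "loa_lower_cm2": -9.22,
 "loa_upper_cm2": 9.31,
 "n": 68,
 "r_squared": 0.998,
 "residual_sd": 5.0,
 "response": "sat_manual_cm2",
 "terms": {
  "age_adult": 3.337,
  "intercept": 0.67,
  "sat_otsu_cm2": 1.037
 },
 "weighting": "inverse_sex_age_frequency"
}
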