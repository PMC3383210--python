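{
  "model": "real (training set)",
  "n": 26,
  "p": 3,
  "r2": 0.809,
  "sec": 0.264,
  "f_value": 31.089,
  "f_crit": 3.049,
  "alpha": 0.05,
  "q2_loo": 0.626,
  "sev": 0.340,
  "press": 3.000,
  "ssy": 8.026,
  "intercept": 55.156,
  "raw_coefficients": {
    "SOFT": 0.450,
    "EEig01x": -2.293,
    "alpha_xx": 0.013,
    "q10NBO": 61.930,
    "q2NBO": 14.508,
    "SsssN(oth)": -8.637
  },
  "standardized_coefficients": {
    "EEig01x": -0.579,
    "SOFT": 0.599,
    "alpha_xx": 0.362,
    "q10NBO": 0.149,
    "q2NBO": 0.322,
    "SsssN(oth)": -0.278
  },
  "test_ids": ["A0", "B5", "C2", "C4", "C9"],
  "external": {
    "r2_pred": 0.641,
    "sep": 0.325,
    "k": 1.017,
    "k_prime": 0.981,
    "abs_r2_diff": 0.004
  }
}
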