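{
  "model": "auxiliary (full data set)",
  "n": 31,
  "p": 3,
  "r2": 0.783,
  "sec": 0.276,
  "f_value": 32.521,
  "f_crit": 2.960,
  "alpha": 0.05,
  "q2_loo": 0.618,
  "sev": 0.342,
  "press": 3.621,
  "ssy": 9.491,
  "intercept": 64.222,
  "raw_coefficients": {
    "SOFT": 0.394,
    "EEig02r": -2.198,
    "alpha_xx": 0.014,
    "q10NBO": 80.105,
    "q2NBO": 11.339,
    "SsssN(oth)": -9.218
  },
  "standardized_coefficients": {
    "EEig02r": -0.549,
    "SOFT": 0.545,
    "alpha_xx": 0.377,
    "q10NBO": 0.238,
    "q2NBO": 0.250,
    "SsssN(oth)": -0.314
  },
  "wold_threshold": 0.274,
  "explained_x_variance": [18.043, 31.298, 22.504],
  "cumulative_x_variance": 71.845
}
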