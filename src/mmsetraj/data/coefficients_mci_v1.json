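{
  "group": "MCI",
  "outcome": "MMSE",
  "bounds": [0, 30],
  "time_center": 2.3,
  "entries": {
    "intercept": 12.9446,
    "t1": -1.6700,
    "t2": -0.2090,
    "t3": 0.0141,
    "age": 0.0147,
    "sex": 0.4329,
    "mmse_bl": 0.5283,
    "log_ptau": -1.1162,
    "abeta42": 0.0008,
    "age:t": 0.0188,
    "abeta42:t": 0.0006,
    "sex:t": 0.2884,
    "log_ptau:t": -0.3894
  },
  "se": {
    "intercept": 2.4238,
    "t1": 1.1730,
    "t2": 0.0486,
    "t3": 0.0091,
    "age": 0.0239,
    "sex": 0.3227,
    "mmse_bl": 0.0534,
    "log_ptau": 0.4153,
    "abeta42": 0.0008,
    "age:t": 0.0142,
    "abeta42:t": 0.0005,
    "sex:t": 0.1926,
    "log_ptau:t": 0.2484
  },
  "notes": "Pooled fixed effects of the published backward-selected biomarker model for amyloid-positive MCI. Time polynomial terms use time centered by subtracting 2.3 years; interaction terms multiply the same centered time. Sex is coded 1 = male (reference female); pTau enters as the natural log of the pg/mL concentration."
}
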