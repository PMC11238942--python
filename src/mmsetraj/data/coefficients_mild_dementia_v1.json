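{
  "group": "mild_dementia",
  "outcome": "MMSE",
  "bounds": [0, 30],
  "time_center": 2.3,
  "entries": {
    "intercept": -10.2450,
    "t1": -9.9597,
    "t2": -0.2196,
    "t3": 0.0227,
    "age": 0.1020,
    "sex": -0.0811,
    "mmse_bl": 1.0006,
    "apoe4": 0.5419,
    "log_ptau": -1.0403,
    "abeta42": 0.0019,
    "age:t": 0.0376,
    "mmse_bl:t": 0.1299,
    "apoe4:t": 0.4768,
    "abeta42:t": 0.0009
  },
  "se": {
    "intercept": 2.4825,
    "t1": 1.4078,
    "t2": 0.0582,
    "t3": 0.0139,
    "age": 0.0274,
    "sex": 0.2718,
    "mmse_bl": 0.0561,
    "apoe4": 0.2842,
    "log_ptau": 0.2990,
    "abeta42": 0.0010,
    "age:t": 0.0156,
    "mmse_bl:t": 0.0345,
    "apoe4:t": 0.1636,
    "abeta42:t": 0.0006
  },
  "notes": "Pooled fixed effects of the published backward-selected biomarker model for amyloid-positive mild dementia. Time polynomial terms use time centered by subtracting 2.3 years; interaction terms multiply the same centered time. Sex is coded 1 = male (reference female); pTau enters as the natural log of the pg/mL concentration."
}
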