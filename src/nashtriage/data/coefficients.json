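{
 "nis4": {
  "beta0": -8.498747,
  "beta1": 4.060406,
  "beta2": 0.760536,
  "beta3": 2.296825,
  "beta4": 0.245169,
  "variant": "nis4",
  "provenance": "synthetic-calibration-v1 (statsmodels Logit fit on default generator cohort, n=20000, seed=20230809)"
 },
 "nis2plus": {
  "beta0": -5.189158,
  "beta1": 4.260037,
  "beta2": 2.308206,
  "beta3": -0.164025,
  "beta4": -0.280293,
  "variant": "nis2plus",
  "provenance": "synthetic-calibration-v1 (statsmodels Logit fit on default generator cohort, n=20000, seed=20230809)"
 }
}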