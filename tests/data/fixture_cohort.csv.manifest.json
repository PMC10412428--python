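{
 "config": {
  "age_ge65": [
   69.0,
   3.0,
   65,
   75
  ],
  "age_lt65": [
   50.0,
   10.0,
   18,
   64
  ],
  "biomarkers": {
   "a2m": {
    "family": "lognormal",
    "ge65": {
     "neg": [
      1.9,
      1.5,
      2.4
     ],
     "pos": [
      2.4,
      1.9,
      3.1
     ]
    },
    "lt65": {
     "neg": [
      1.9,
      1.5,
      2.4
     ],
     "pos": [
      2.4,
      1.9,
      3.1
     ]
    }
   },
   "albumin": {
    "family": "normal",
    "ge65": {
     "neg": [
      4.35,
      0.35
     ],
     "pos": [
      4.25,
      0.38
     ]
    },
    "lt65": {
     "neg": [
      4.35,
      0.35
     ],
     "pos": [
      4.25,
      0.38
     ]
    }
   },
   "alt": {
    "family": "lognormal",
    "ge65": {
     "neg": [
      30.0,
      21.0,
      43.0
     ],
     "pos": [
      50.0,
      35.0,
      68.0
     ]
    },
    "lt65": {
     "neg": [
      36.31578947368421,
      25.42105263157895,
      52.05263157894737
     ],
     "pos": [
      60.526315789473685,
      42.368421052631575,
      82.3157894736842
     ]
    }
   },
   "ast": {
    "family": "lognormal",
    "ge65": {
     "neg": [
      26.0,
      19.0,
      34.0
     ],
     "pos": [
      40.0,
      30.0,
      59.0
     ]
    },
    "lt65": {
     "neg": [
      27.677419354838708,
      20.225806451612904,
      36.19354838709677
     ],
     "pos": [
      42.58064516129032,
      31.93548387096774,
      62.806451612903224
     ]
    }
   },
   "bmi": {
    "family": "normal",
    "ge65": {
     "neg": [
      31.6,
      5.0
     ],
     "pos": [
      32.1,
      5.3
     ]
    },
    "lt65": {
     "neg": [
      33.7,
      5.0
     ],
     "pos": [
      34.2,
      5.3
     ]
    }
   },
   "fpg": {
    "family": "lognormal",
    "ge65": {
     "neg": [
      5.55,
      4.94,
      6.57
     ],
     "pos": [
      6.05,
      5.2,
      7.37
     ]
    },
    "lt65": {
     "neg": [
      5.148103448275862,
      4.582275862068966,
      6.094241379310345
     ],
     "pos": [
      5.611896551724137,
      4.823448275862069,
      6.836310344827586
     ]
    }
   },
   "ha": {
    "family": "lognormal",
    "ge65": {
     "neg": [
      45.0,
      28.0,
      72.0
     ],
     "pos": [
      90.0,
      55.0,
      150.0
     ]
    },
    "lt65": {
     "neg": [
      45.0,
      28.0,
      72.0
     ],
     "pos": [
      90.0,
      55.0,
      150.0
     ]
    }
   },
   "hba1c": {
    "family": "normal",
    "ge65": {
     "neg": [
      6.19,
      0.93
     ],
     "pos": [
      6.45,
      1.0
     ]
    },
    "lt65": {
     "neg": [
      6.010000000000001,
      0.93
     ],
     "pos": [
      6.2700000000000005,
      1.0
     ]
    }
   },
   "mir34a": {
    "family": "lognormal",
    "ge65": {
     "neg": [
      1.0,
      0.72,
      1.4
     ],
     "pos": [
      1.9,
      1.25,
      2.9
     ]
    },
    "lt65": {
     "neg": [
      1.0,
      0.72,
      1.4
     ],
     "pos": [
      1.9,
      1.25,
      2.9
     ]
    }
   },
   "piiinp": {
    "family": "lognormal",
    "ge65": {
     "neg": [
      8.0,
      6.0,
      11.0
     ],
     "pos": [
      11.0,
      8.0,
      15.0
     ]
    },
    "lt65": {
     "neg": [
      8.0,
      6.0,
      11.0
     ],
     "pos": [
      11.0,
      8.0,
      15.0
     ]
    }
   },
   "platelets": {
    "family": "normal",
    "ge65": {
     "neg": [
      223.0,
      72.0
     ],
     "pos": [
      213.0,
      62.0
     ]
    },
    "lt65": {
     "neg": [
      248.0,
      72.0
     ],
     "pos": [
      238.0,
      62.0
     ]
    }
   },
   "timp1": {
    "family": "lognormal",
    "ge65": {
     "neg": [
      230.0,
      190.0,
      280.0
     ],
     "pos": [
      290.0,
      235.0,
      360.0
     ]
    },
    "lt65": {
     "neg": [
      230.0,
      190.0,
      280.0
     ],
     "pos": [
      290.0,
      235.0,
      360.0
     ]
    }
   },
   "ykl40": {
    "family": "lognormal",
    "ge65": {
     "neg": [
      75.0,
      50.0,
      110.0
     ],
     "pos": [
      125.0,
      82.0,
      190.0
     ]
    },
    "lt65": {
     "neg": [
      75.0,
      50.0,
      110.0
     ],
     "pos": [
      125.0,
      82.0,
      190.0
     ]
    }
   }
  },
  "diabetes_frac": {
   "ge65": {
    "neg": 0.44,
    "pos": 0.59
   },
   "lt65": {
    "neg": 0.33,
    "pos": 0.48
   }
  },
  "fibrosis_weights": {
   "neg": {
    "0": 21.0,
    "1": 36.0,
    "2": 12.0,
    "3": 26.0,
    "4": 6.0
   },
   "pos": {
    "2": 32.0,
    "3": 58.0,
    "4": 11.0
   }
  },
  "frac_ge65": 0.19970774476376035,
  "latent_loading": 0.5,
  "latent_markers": [
   "mir34a",
   "ykl40",
   "ast",
   "alt"
  ],
  "male_frac": {
   "ge65": {
    "neg": 0.73,
    "pos": 0.5
   },
   "lt65": {
    "neg": 0.62,
    "pos": 0.62
   }
  },
  "max_gap_days": 90,
  "n": 50,
  "nas_weights": {
   "neg": {
    "0": 14.0,
    "1": 14.0,
    "2": 25.5,
    "3": 25.5,
    "4": 10.5,
    "5": 10.5,
    "6": 0.3333333333333333,
    "7": 0.3333333333333333,
    "8": 0.3333333333333333
   },
   "pos": {
    "4": 26.5,
    "5": 26.5,
    "6": 15.666666666666666,
    "7": 15.666666666666666,
    "8": 15.666666666666666
   }
  },
  "prevalence_ge65": 0.47073170731707314,
  "prevalence_lt65": 0.4576993304930006,
  "provenance": "synthetic-calibration-v1",
  "target_auroc": {
   "nis2plus": 0.83
  }
 },
 "n": 50,
 "seed": 50,
 "sha256": "89f0585daac838a5b07c75033aa5bd26d036e0603fef9edb065e29a946f7aca3"
}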