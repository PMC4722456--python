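{
  "wild-type": {
    "label": "wild-type",
    "k1k2_acto": {"value": 0.70, "sd": 0.10},
    "k_ad": {"value": 406.0, "sd": 25.0},
    "k_minus_d": {"value": 8.0, "sd": 0.5},
    "k1k2_s1": {"value": 6.0, "sd": 0.8},
    "k_hyd_sum": {"value": 308.0, "sd": 35.0},
    "k05": {"value": 53.0, "sd": 12.0},
    "vmax": {"value": 2.54, "sd": 0.29},
    "km": {"value": 5.77, "sd": 0.83},
    "basal_ca": {"value": 5.32, "sd": 0.62},
    "basal_mg": {"value": 0.092, "sd": 0.014}
  },
  "R759E": {
    "label": "R759E",
    "k1k2_acto": {"value": 0.72, "sd": 0.09},
    "k_ad": {"value": 428.0, "sd": 20.0},
    "k_minus_d": {"value": 7.0, "sd": 0.4},
    "k1k2_s1": {"value": 2.7, "sd": 0.9},
    "k_hyd_sum": {"value": 223.0, "sd": 28.0},
    "k05": {"value": 85.0, "sd": 30.0},
    "vmax": {"value": 0.79, "sd": 0.23},
    "km": {"value": 4.99, "sd": 1.23},
    "basal_ca": {"value": 2.26, "sd": 0.51},
    "basal_mg": {"value": 0.052, "sd": 0.016}
  },
  "R759E/N509K": {
    "label": "R759E/N509K",
    "k1k2_acto": {"value": 0.70, "sd": 0.05},
    "k_ad": {"value": 421.0, "sd": 41.0},
    "k_minus_d": {"value": 6.0, "sd": 0.3},
    "k1k2_s1": {"value": 10.0, "sd": 1.0},
    "k_hyd_sum": {"value": 404.0, "sd": 111.0},
    "k05": {"value": 41.0, "sd": 8.0},
    "vmax": {"value": 1.31, "sd": 0.38},
    "km": {"value": 3.58, "sd": 1.53},
    "basal_ca": {"value": 3.65, "sd": 0.69},
    "basal_mg": {"value": 0.073, "sd": 0.017}
  }
}
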