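{
  "config": {
    "age_mean": 29.0,
    "age_parity_load": 0.6,
    "age_range": [
      18.0,
      43.0
    ],
    "age_sd": 6.0,
    "asset_p": 0.6153846153846154,
    "infant_age_geom_p": 0.16,
    "m_model": {
      "caesarean": -1.5,
      "educ_grade12": 1.0,
      "hps_high": 2.0,
      "intercept": 48.0,
      "x": 4.0,
      "z_age": 1.0
    },
    "mediator_scale": "raw",
    "n": 2000,
    "parity_probs": [
      0.34,
      0.31,
      0.24,
      0.08,
      0.03
    ],
    "prevalences": {
      "caesarean": 0.29,
      "educ_grade12": 0.64,
      "employed": 0.25,
      "hiv": 0.2,
      "hps_high": 0.76,
      "hsi_high": 0.7
    },
    "residual_sd": 6.0,
    "x_model": {
      "educ_grade12": 0.2,
      "hps_high": 0.4,
      "intercept": -0.7169,
      "z_assets": 0.1
    },
    "y_model": {
      "caesarean": -0.4,
      "educ_grade12": 0.3,
      "hiv": -0.5,
      "hps_high": 0.4,
      "infant_age_c": -0.2,
      "intercept": 0.809,
      "m": 0.8,
      "x": 0.5,
      "z_age": 0.2
    }
  },
  "oracle_seed": 5,
  "truth": {
    "method": "direct simulation of counterfactual mediators from the true structural equations; outcome expectation taken analytically and standardized over the confounder draw",
    "oracle_n": 4000000,
    "true_nde": 0.09764436328427695,
    "true_nie": 0.03869889793494452,
    "true_prop_mediated": 0.2838343280693715,
    "true_tce": 0.13634326121922147
  }
}
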