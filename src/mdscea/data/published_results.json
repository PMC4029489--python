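{
  "_comment": "Lifetime results as published by the Spanish cost-effectiveness study of azacitidine in high-risk MDS (2012 euros, 3% discounting). Per-arm values as displayed in the study's results table; 'prose_*' entries are the rounded figures quoted in its running text. These are reference fixtures for validation, not model outputs.",
  "comparisons": {
    "BSC": {
      "aza_cost": 107168, "comp_cost": 35090,
      "aza_ly": 4.05, "comp_ly": 1.88,
      "aza_qaly": 3.06, "comp_qaly": 1.24,
      "icer_per_ly": 33111, "icer_per_qaly": 39610,
      "prose_delta_cost": 72112
    },
    "LDC": {
      "aza_cost": 115537, "comp_cost": 53184,
      "aza_ly": 4.45, "comp_ly": 2.06,
      "aza_qaly": 3.39, "comp_qaly": 1.36,
      "icer_per_ly": 25953, "icer_per_qaly": 30531,
      "prose_delta_cost": 61929
    },
    "SDC": {
      "aza_cost": 106422, "comp_cost": 59725,
      "aza_ly": 3.96, "comp_ly": 1.49,
      "aza_qaly": 2.94, "comp_qaly": 0.98,
      "icer_per_ly": 18884, "icer_per_qaly": 23804
    },
    "CCR": {
      "aza_cost": 108605, "comp_cost": 43170,
      "aza_ly": 4.11, "comp_ly": 1.85,
      "aza_qaly": 3.11, "comp_qaly": 1.22,
      "icer_per_ly": 28891, "icer_per_qaly": 34673,
      "prose_delta_cost": 65436
    }
  },
  "published_increments": {
    "delta_qaly_vs_bsc": 1.82,
    "delta_qaly_vs_ldc": 2.03,
    "delta_qaly_vs_ccr": 1.89,
    "delta_ly_vs_ldc": 2.39,
    "delta_ly_vs_ccr": 2.26
  },
  "prose_cycle_costs": {"AZA_on": 4911, "LDC_on": 2671, "BSC": 1772},
  "prose_ae_costs_per_cycle": {"AZA": 330, "BSC": 345, "LDC": 627},
  "psa_probability_cost_effective_at_50000": {"CCR": 96.49, "BSC": 83.21, "LDC": 91.21},
  "patient_counts": {"AZA": 110, "BSC": 79, "LDC": 38, "SDC": 20},
  "wtp_threshold_per_qaly": 50000
}
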