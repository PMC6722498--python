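{
  "description": "Published summary numbers for the 287-patient tamoxifen verification cohort: diplotype-group counts, the two ranked model traces, and final model performance. Used as fixed inputs for desk-scale re-derivations; the patient-level data are not included.",
  "cohort": {
    "n_total": 287,
    "n_mr_below": 175,
    "n_mr_above": 112,
    "n_complete_cases": 262,
    "diplotype_counts": {
      "NM/UM": 18,
      "NM/NM": 90,
      "NM/IM": 44,
      "NM/PM": 99,
      "IM/IM": 3,
      "IM/PM": 12,
      "PM/PM": 21
    }
  },
  "association": {
    "n_variants_tested": 18,
    "alpha": 0.05,
    "lambda_gc": 1.076
  },
  "approach1_trace": {
    "variables": ["CYP2D6_genotype", "rs7245", "rs6950784", "rs1320308", "rs11786748"],
    "minus2ll_reduced": [254.137, 238.013, 223.925, 214.671, 210.654],
    "r2_cumulative": [0.427, 0.482, 0.527, 0.556, 0.568],
    "auc_cumulative": [0.758, 0.842, 0.871, 0.879, 0.880]
  },
  "approach2_trace": {
    "variables": ["rs8138080", "rs1320308", "rs6950784", "rs7245", "rs1065852", "rs11786748"],
    "minus2ll_reduced": [278.432, 264.234, 255.872, 247.300, 242.012, 237.058],
    "r2_cumulative": [0.337, 0.390, 0.420, 0.450, 0.468, 0.485],
    "auc_cumulative": [0.718, 0.795, 0.819, 0.830, 0.817, 0.813]
  },
  "model1": {
    "auc": 0.879,
    "sensitivity_pct": 87.8,
    "specificity_pct": 70.8,
    "ppv_pct": 81.6,
    "npv_pct": 79.8,
    "counts": {"n_below": 156, "detected": 137, "n_above": 106, "false_positive": 31}
  },
  "model2": {
    "auc": 0.830,
    "sensitivity_pct": 80.1,
    "specificity_pct": 64.2,
    "ppv_pct": 76.7,
    "npv_pct": 68.7
  }
}
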