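{
  "abba_baba_nuclear": {
    "comment": "ABBA-BABA counts for the festus-gilaensis-roberti(-ophrys outgroup) nuclear test",
    "taxa": {"P1": "H_festus", "P2": "H_gilaensis", "P3": "H_roberti", "O": "H_ophrys"},
    "n_abba": 1051,
    "n_baba": 476,
    "printed_D": 0.377
  },
  "abba_baba_mitochondrial": {
    "comment": "same test on mtDNA, taxa reordered to the mitochondrial tree; no bias expected",
    "taxa": {"P1": "H_festus", "P2": "H_roberti", "P3": "H_gilaensis", "O": "H_ophrys"},
    "n_abba": 89,
    "n_baba": 88,
    "printed_D": 0.006
  },
  "bonferroni_battery": {
    "comment": "62 D/D_FOIL chi-square tests at family alpha 0.05",
    "n_comparisons": 62,
    "family_alpha": 0.05,
    "printed_threshold": 0.0008
  },
  "excess_cf_americanus": {
    "comment": "ophrys+americanus+sansoni CF vs the mirror tarsalis+americanus+sansoni CF",
    "universe": ["H_ophrys", "H_tarsalis", "H_americanus", "H_sansoni", "H_aestus", "H_signatus"],
    "focal": {"taxa": ["H_ophrys", "H_americanus", "H_sansoni"], "cf": 0.305, "ci": [0.272, 0.339], "n_genes": 679},
    "alternatives": [
      {"taxa": ["H_tarsalis", "H_americanus", "H_sansoni"], "cf": 0.092, "ci": [0.092, 0.092], "n_genes": 679}
    ],
    "printed_excess_pct": 21
  },
  "excess_cf_roberti": {
    "comment": "roberti+clypeatus-group CF vs roberti+viridipes and roberti+coecatus CFs",
    "universe": ["H_roberti", "H_gilaensis", "H_clypeatus", "H_jucundus", "H_festus", "H_ophrys"],
    "focal": {"taxa": ["H_roberti", "H_gilaensis", "H_clypeatus"], "cf": 0.188, "ci": [0.17, 0.205], "n_genes": 517},
    "alternatives": [
      {"taxa": ["H_roberti", "H_jucundus"], "cf": 0.052, "ci": [0.039, 0.06], "n_genes": 517},
      {"taxa": ["H_roberti", "H_festus"], "cf": 0.041, "ci": [0.027, 0.058], "n_genes": 517}
    ],
    "printed_excess_pct": 14
  },
  "excess_cf_aestus": {
    "comment": "aestus+tarsalis CF vs the mirror aestus+ophrys CF (0.039 as the intended value)",
    "universe": ["H_ophrys", "H_tarsalis", "H_americanus", "H_sansoni", "H_aestus", "H_signatus"],
    "focal": {"taxa": ["H_aestus", "H_tarsalis"], "cf": 0.136, "ci": [0.112, 0.162], "n_genes": 679},
    "alternatives": [
      {"taxa": ["H_aestus", "H_ophrys"], "cf": 0.039, "ci": [0.023, 0.055], "n_genes": 679}
    ],
    "printed_excess_pct": 10
  }
}
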