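{
  "schema_version": 1,
  "seed": 20260301,
  "simulate": {
    "length": 25000,
    "gc_fraction": 0.36,
    "coverage_per_strand": 30,
    "log_sigma": 0.5,
    "outlier_prob": 0.001,
    "outlier_scale": 50,
    "neighbor_mismatch_prob": 0.01,
    "plants": [
      {"motif": "GATC", "focal": 2, "count": 60,
       "modification_multiplier": 8.57,
       "context_multipliers": {"1": 1.03},
       "modify_all_occurrences": true},
      {"motif": "ATGCAT", "focal": 5, "count": 40,
       "modification_multiplier": 1.0}
    ]
  },
  "thresholds": {
    "min_valid": 25,
    "pct": 1.0,
    "flank": 10,
    "window": 41,
    "alpha": 0.001,
    "fold_threshold": 2.0,
    "coverage_grid": [25, 30, 35]
  },
  "motifs": [
    {"iupac": "GATC", "focal": 2},
    {"iupac": "ATGCAT", "focal": 5}
  ],
  "annotations": null
}
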