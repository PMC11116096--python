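{
  "generator": {
    "n_families": 2000,
    "n_waves": 2,
    "sibling_prob": 0.15,
    "missing_rate": 0.02,
    "seed": 1
  },
  "preprocess": {"seed": 2, "td_threshold": 60},
  "fit": {"seed": 3, "folds": 10},
  "associate": {"fdr": 0.05, "family": "per-sex-model"}
}
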