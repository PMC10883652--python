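{
 "type": "object",
 "required": ["version", "config", "stages"],
 "properties": {
  "version": {"type": "string"},
  "config": {
   "type": "object",
   "required": ["table_path", "metadata_path", "out_dir", "seed"]
  },
  "stages": {
   "type": "object",
   "required": ["load", "filter", "relative_abundance", "alpha_diversity", "beta_diversity", "differential_abundance"],
   "properties": {
    "load": {"type": "object", "required": ["n_features", "n_samples"]},
    "filter": {"type": "object", "required": ["n_features"]},
    "relative_abundance": {"type": "object", "required": ["n_features"]},
    "alpha_diversity": {"type": "object", "required": ["n_comparisons", "significant"]},
    "beta_diversity": {"type": "object", "required": ["anosim_r", "anosim_p", "anosim_method"]},
    "differential_abundance": {"type": "object", "required": ["n_tested", "significant_after_bonferroni", "lefse_flagged"]},
    "classifier": {"type": "object", "required": ["n_features_selected", "train_accuracy", "test_accuracy"]}
   }
  }
 }
}
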