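# Demo configuration for the full pipeline (small sizes, runs in ~1 min):
#   lymphomir run-all --config examples/demo.yaml --out out/
seed: 7
output_dir: out
synthetic:
  cohort:
    n_per_class: {RLN: 19, nTFHL: 49, nPTCL: 20}
    n_mirnas: 80
    n_low_detection: 20
    effects:
      n_shared: 22
      n_ntfhl: 3
      n_nptcl: 3
      shift_range: [1.5, 2.0]
  target_map:
    n_genes: 1000
    targets_per_mirna: [10, 40]
  gene_sets:
    n_null_sets: 20
    set_size: [20, 40]
comparisons: [grouped, nTFHL, nPTCL]
lr_grid:
  feature_percentages: [10.0, 20.0]
  inv_regularization: [0.01, 1.0, 100.0]
  l1_ratios: [0.0, 0.5, 1.0]
rf_grid:
  max_depths: [3, 4]
  bootstrap: [true]
  max_features: [sqrt]
  criterion: [gini]
  n_trees: 100
cv:
  outer_folds: 5
  inner_folds_lr: 10
  inner_folds_rf: 3
enrichment:
  n_permutations: 499
importance_repeats: 5
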