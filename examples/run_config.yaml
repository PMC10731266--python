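# Example end-to-end run on synthetic data (the default input mode).
# Run with:  somportrait run --config examples/run_config.yaml
seed: 17
outdir: somportrait_run
synthetic: true

generator:
  n_genes: 5000
  baseline_log_mean: 1.5
  baseline_log_sd: 0.8
  noise_sd: 0.25
  cultivar_sd: 0.05

som:
  rows: 40
  cols: 40
  n_epochs: 50
  radius_end: 0.5
  init: pca-linear

threshold_quantile: 0.98
min_units: 4
tree_metric: correlation
tree_space: metagene
clade_jaccard: 0.5
top_k_sets: 3
top_k_genes: 20
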