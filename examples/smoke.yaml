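# Small end-to-end configuration: simulate a cohort, run the full ablation
# for the raw and VAE pathways with two classifiers, write reports.
simulation:
  n_patients: 150
  prevalence: 0.77
  effect_size: 3.0
  n_features: {cln: 10, cnv: 60, dna: 60, mir: 30, mrna: 60}
  wsi_patches: 6
  wsi_dim: 16
  seed: 1
preprocess:
  top_k: 40
wsi:
  fraction: 0.34
  cap: 3
  patch_dim: 8
  final_dim: 16
reducer:
  vae:
    epochs: 30
    hidden_widths: [32]
    learning_rate: 0.003
ablation:
  feature_kinds: [raw, vae]
  classifiers: [rbf_svm, random_forest]
  max_arity: 3
protocol:
  n_folds: 10
  seed: 1
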