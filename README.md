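# survfuse

Multi-modal survival classification for breast-cancer cohorts: per-modality
preprocessing, three feature pathways (raw, PCA, log-cosh VAE), fusion of up
to six modalities, and a full modality-combination ablation with stability
analysis.

## The problem

A TCGA-BRCA-style cohort observes each patient through up to six views —
clinical covariates, GISTIC2-thresholded copy number, DNA-methylation beta
values, miRNA expression, mRNA expression, and whole-slide-image (WSI)
patch embeddings — with not every patient present in every view.  The task
is binary 5-year survival prediction: short-term survivors (death before 60
months, label 1) versus long-term survivors (label 0).  The question the
ablation answers is whether fusing more modalities makes the classifiers
better *and more stable*, measured as the across-combination standard
deviation of the metrics shrinking as modalities are added.

## The model

Per modality m with features x_m, a variational autoencoder encodes
x_m into a Gaussian posterior q_φ(z_m | x_m) and decodes x̂_m, trained to
minimize

    L_m = (1/a) Σ_i log cosh(a (x_i − x̂_i)) + D_KL(q_φ(z_m|x_m) ‖ N(0, I)),

the log-cosh reconstruction being quadratic near zero residual and linear
in the tails.  Latent means μ_m (4 dims for clinical, 32 otherwise) are the
VAE features; PCA at 95% explained variance and the preprocessed raw
matrices are the two baselines.  Fused feature sets (column concatenation)
are scored by four soft-margin SVM kernels and a random forest under
ten-fold stratified cross-validation with per-fold minority upsampling,
reporting Acc, Pre, Sn and f1 with short-term as the positive class.

A seeded synthetic-cohort generator plants one shared latent signal across
all six views so that every stage — imputation, selection, WSI aggregation,
reduction, fusion, ablation — is testable end to end without any download.

## Worked example

```python
from survfuse.study import run_reference_ablation

report, agg = run_reference_ablation(seed=1)
print(agg[["arity", "n_combinations", "mean_f1", "std_f1"]].to_string(index=False))
```

prints

```
 arity  n_combinations   mean_f1    std_f1
     1               6  0.983228  0.036535
     2              15  0.999845  0.000395
     3              20  1.000000  0.000000
     4              15  1.000000  0.000000
     5               6  1.000000  0.000000
     6               1  1.000000  0.000000
```

Each row aggregates the VAE-pathway random-forest results across all
combinations of that arity on a 600-patient synthetic cohort with a planted
class signal (δ = 3) shared by all six modalities.  Mean f1 rises toward the
ceiling as modalities are fused, and the across-combination standard
deviation of f1 collapses from 0.037 (uni-modal: single views differ in how
well they carry the signal) to 0 — the stability signature of complementary
modalities.  On a matched null cohort (δ = 0, balanced classes) the same
pipeline stays at chance accuracy (≈ 0.51).

The same study is available from a shell:

```bash
survfuse simulate --out cohort/ --seed 1
survfuse run --config examples/smoke.yaml --out results/ --seed 1
```

producing `records.csv` (one row per combination × pathway × classifier),
`aggregates.json`, a `table2_style.csv` summary, and `run_manifest.json`
with every seed used.

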