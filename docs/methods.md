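# Methods

## Problem and model

`survfuse` implements a multi-modal survival classification pipeline for
breast-cancer cohorts of the TCGA-BRCA type.  Each patient is observed
through up to six views: clinical covariates (categorical integers plus a
continuous age), GISTIC2-thresholded copy-number calls in {−2, −1, 0, 1, 2},
DNA-methylation beta values in [0, 1], non-negative miRNA expression,
continuous mRNA expression (later trichotomized), and whole-slide-image
(WSI) patch-embedding bags.  The prediction target is the binary 5-year
(60-month) survival label: short-term survivor (death event before 60
months) is the positive class 1; follow-up past 60 months is class 0.
Patients censored before 60 months carry no label under this rule; by
default they are excluded (`censored_policy="exclude"`), with an option to
count them as long-term.  The exclusion is a deliberate design choice in an
underdetermined corner of the labelling rule; both policies are exposed.

Three feature pathways feed the classifiers:

- **raw** — the preprocessed matrices themselves;
- **pca** — per-modality PCA keeping the smallest number of components
  whose cumulative explained variance reaches 95%;
- **vae** — per-modality log-cosh variational autoencoders with latent
  dimension 4 (clinical) or 32 (all other modalities).

Per modality combination, feature blocks are concatenated in sorted-tag
order and scored by soft-margin SVMs (RBF, linear, polynomial, sigmoid) and
a random forest under ten-fold stratified cross-validation with per-fold
minority upsampling.  The ablation enumerates all 63 modality subsets and
the stability analysis tracks the across-combination standard deviation of
each metric per arity.

## Preprocessing

Fixed order per modality: drop features with strictly more than 10% missing
cells (exactly 10% is kept — the rule is "more than"); impute the rest by an
inverse-distance-weighted mean over the k = 10 nearest patients (Euclidean
distance on mutually observed features; `sklearn.impute.KNNImputer` with
distance weights); min-max the clinical age column to [0, 1]; trichotomize
mRNA per gene at z = ±1.0 (under-/baseline/over-expressed; the threshold is
configurable because the literature convention varies); drop zero-variance
features; keep the top-500 features by variance for the high-dimensional
copy-number and mRNA modalities (ties broken lexicographically on feature id
for determinism; a warning fires when the captured variance drops below
98%); finally intersect patient ids across the modalities of a combination
(sorted order).  Imputation never alters observed cells, and intersection is
idempotent and order-independent — both are asserted in tests.

## WSI aggregation

Bags of patch embeddings (2048-d at real scale) are reduced to one vector
per patient: keep the `min(cap, ceil(fraction·n))` densest patches
(defaults 20% / cap 40), pad cyclically to exactly `cap` rows when fewer
survive — cyclic duplication rather than zero-padding, so the pooled PCA
centering is not distorted; PCA the pooled patches of the cohort to 512
dims; concatenate each patient's patches in density-rank order (40 × 512 =
20,480); PCA the cohort's vectors to 800 dims at 95% variance.  The
patch-level PCA is fitted cohort-wide, not per slide.  Synthetic cohorts run
the same code at reduced sizes.

## The log-cosh VAE

Encoder and decoder are symmetric multilayer perceptrons (tanh hidden
layers; linear μ and log σ² heads; linear decoder output), trained on

    L = (1/a) Σ_i log cosh(a (x_i − x̂_i))  +  KL(q(z|x) ‖ N(0, I)),

both terms summed over features/latent dims and averaged over the batch,
with reparameterized sampling z = μ + σ ⊙ ε.  The log-cosh reconstruction
is quadratic (≈ a r²/2) for |a r| ≪ 1 and linear (≈ |r| − log 2 / a) for
|a r| ≫ 1, i.e. L2-like near zero and L1-like in the tails; it is computed
overflow-safely as |t| + log1p(e^(−2|t|)) − log 2.

Because no deep-learning framework is a dependency, the network is plain
NumPy with hand-derived backpropagation and Adam (lr 1e−3, batch 64, max
200 epochs, patience 20 — all configurable).  The analytic gradients are
verified against central finite differences to a relative error below 1e−4,
which is the strongest available correctness check for this component.

Choices where the design was open:

- **a = 10** by default.  With inputs min-max scaled to [0, 1] (scaling
  stored with the model), residuals live in [−1, 1], so a = 10 puts typical
  residuals in the transition region rather than the purely quadratic one.
- **Inputs scaled to [0, 1] per feature** before fitting, keeping the
  reconstruction/KL balance comparable across modalities with very
  different native ranges.
- **Downstream features are the posterior means μ**, never sampled z:
  deterministic, and the standard choice when latents feed a classifier.
- **Unweighted KL** (no β or annealing).  A consequence worth knowing: for
  very narrow matrices (≲ 30 features) the summed reconstruction term is
  small relative to the KL and the posterior can collapse toward the prior.
  This is a property of the objective, not a bug; at the feature counts the
  pipeline actually feeds the VAEs (≥ 21, typically 100–500) the latent
  space is used and reconstruction succeeds (tested with an exact
  low-rank-planted oracle at 100 features: residual variance < 10% of data
  variance).
- **Early stopping** on the training epoch loss (no validation split):
  patience 20 on a 1e−6 improvement threshold.

## PCA conventions

Full-SVD PCA; the component count is the smallest reaching the requested
cumulative explained-variance fraction, capped by matrix rank and by the
optional hard cap used in the WSI pathway.  Sign convention: each
component's largest-magnitude loading is positive, making every projection
deterministic.  Stored explained fractions match an independent
recomputation from the projected data to 1e−8 (Pythagorean identity).

## Evaluation protocol

Stratified ten-fold CV (seeded shuffle); per-fold class counts are within
one sample of exact proportionality.  Training folds are balanced by
resampling minority rows with replacement; test folds are never modified,
and train/test disjointness is asserted on every fold.  Classifiers:
soft-margin SVMs with C = 0.1 (a deliberately small penalty) and
gamma = 1/n_features for the kernels that use it, polynomial degree 3;
random forest with 100 trees and √p candidate features per split.  Metrics
use the clinical positive-class convention (short-term = 1): Acc, Pre =
tp/(tp+fp), Sn = tp/(tp+fn), f1 = 2·Pre·Sn/(Pre+Sn); 0/0 is defined as 0
with a warning.  Reported values are macro averages over folds; the
per-fold values and confusion counts are retained.

Reducer fit scope: `full` (default) fits PCA/VAE on all patients of a
modality before CV — the conventional protocol in this literature, but
optimistic, as
unsupervised information from test patients enters the reducers; `per-fold`
refits reducers on each training fold only (leakage-safe).  The switch is
global and recorded in the run manifest.

## Synthetic cohort generator

The generator emulates the *structure* of the real data, not its marginal
distributions: a shared latent patient state u ∈ R^8 carries the class
signal (u | label ~ N(±δ/2·1, I), labels Bernoulli(prevalence)), and every
modality observes W·u + ε through its own unit-row random map W and
Gaussian noise ε before squashing into its native domain (thresholds for
copy-number and clinical categories, logistic for beta values, softplus for
miRNA; WSI bags add per-patch noise around the patient's embedding and a
gamma-distributed density per patch).  Survival times are drawn consistent
with the label (deaths uniform on [2, 59.5] months; long-term follow-up
uniform on [60.5, 240] with mixed event status).  Feature cells go missing
i.i.d. (default 2%) and whole patients drop out of a modality at a default
5% absence rate, creating the incomplete multi-view structure the
intersection step resolves.

Default prevalence is 0.77 short-term.  The cohort's class ratio is chosen
so that an all-positive classifier attains precision ≈ 0.77 — the regime in
which near-ceiling sensitivity with ~0.77 precision is the characteristic
signature of the imbalanced task.  All randomness fans out from one seed
through fixed per-stage spawn keys (labels 0, latents 1, survival 2,
modalities 10–15, missingness 30, absence 31), so each stage is
independently reproducible and an identical configuration yields
bit-identical TSV output.

Because one latent u underlies all views, the views are complementary:
fusing more of them averages away per-modality noise.  This is the planted
analogue of the stability claim and what makes "std of metrics shrinks with
arity" a falsifiable property here.  What passing these tests does *not*
show: robustness to real-data pathologies the generator omits — batch
effects, platform differences, non-linear modality interactions, and
informative censoring.

## Reference study sizes

The packaged reference study (`survfuse.study`) runs the full pipeline at
desk scale: n = 600 patients; 150 features for copy-number, methylation and
mRNA, 80 for miRNA, 21 clinical, WSI 8 patches × 32 dims (cap 4, patch PCA
16, final 32); top-variance selection at k = 100; VAE hidden width 64, 60
epochs, lr 3e−3; VAE pathway with a 100-tree random forest over all 63
combinations.  These sizes are the package's chosen reproducible study
conditions; all of them are configuration, and the real-scale defaults
(500-feature selection, 2048-d patches, 40-patch cap, 512/800 PCA) remain
the defaults of the corresponding operations.

## Numerical notes and limitations

- Log-cosh is evaluated in the |t| + log1p(e^(−2|t|)) − log 2 form; KL in
  closed form; both validated against Monte-Carlo/high-precision oracles.
- Variance-ranking and density-ranking ties break deterministically (feature
  id, patch index).
- Degenerate inputs fail loudly: constant columns for min-max, zero-variance
  matrices for PCA, all-missing patients for imputation, empty patient
  intersections, single-class folds.
- The VAE trains on the full objective from epoch 0; there is no KL warm-up,
  so narrow inputs can posterior-collapse (see above).
- Aggregate standard deviations are population (ddof = 0) so the single
  hexa-modal combination reports exactly 0; sample std is available.
- No significance testing between classifiers and no hyperparameter search —
  out of scope by design.
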