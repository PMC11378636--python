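# Methods

## The problem

Comprehensive molecular characterization of cancer cell lines — metabolite
abundance, protein levels, copy number, mutation status, CRISPR gene-effect
scores, drug sensitivity — is expensive, while bulk RNA-seq is routine.
This package predicts those measurement types from gene expression alone,
using a transfer-learning trick to cope with the "big p, little n" regime:
cell-line panels have on the order of a thousand samples, but tumor
compendia have ten thousand, and the two share most of their transcriptional
structure.

## The model

**Domain-similarity feature selection.** For every gene shared by the
source (tumor) and target (cell-line) expression matrices — both in
log2(1+TPM) — a two-sample Kolmogorov–Smirnov test compares the two
per-gene distributions (two-sided, asymptotic p-values: per-gene sample
sizes are in the hundreds-to-thousands regime).  P-values are
Benjamini–Hochberg adjusted (Bonferroni available as a config hook) and the
k genes with the **largest** adjusted p — the most similar distributions —
are kept.  This guards against negative transfer: genes that behave
differently in tumors would actively mislead an encoder destined for cell
lines.  Ties (many adjusted p-values saturate at 1) break by smaller KS
statistic, then lexicographic gene id, so rankings are reproducible across
platforms.  The production k is 5000; the synthetic desk-scale default is
the non-shifted gene count.

**Two-step pre-training.** An autoencoder

    h = s_f(W x + b_x)        encoder, s_f = LeakyReLU(alpha = 0.1)
    x_hat = s_g(W' h + b_h)   decoder, s_g = identity

with layer widths input → 512 → 200 (bottleneck) is trained on the source
domain minimizing the reconstruction loss (1/n) Σᵢ‖xᵢ − x̂ᵢ‖², with 90% of
samples training and 10% validating, returning the best-validation
checkpoint.  The trained source **encoder** weights then initialize a fresh
target-domain autoencoder (the decoder is re-initialized by the default
fan-in-scaled uniform scheme), the autoencoder is trained on the target
domain, and the resulting encoder — provenance `two_step` — is extracted.
Ablation variants `target_only` (no transfer) and `source_only` (tumor
encoder used as-is) exist for comparison.

*Decoder warm-up.* The target phase spends the first 25% of its epoch
budget training only the re-initialized decoder with the transferred
encoder frozen, then trains all layers (gradual unfreezing).  Without this,
early gradients flowing back through a still-random decoder measurably
corrupt the transferred encoder: in linear-probe experiments its
representation quality fell below the source-only encoder's at short
budgets.  The warm-up is internal to the target training step; the total
target epoch budget is unchanged, so budget-matched comparisons remain
fair, and the weight-transfer step itself remains bit-exact.

**Prediction network.** The encoder feeds a 4-layer head: a merge layer
over the 200 bottleneck units, two fully connected layers (128 and 32 by
default; config-exposed since per-measurement-type widths are tuned in
production), and one output unit — identity for regression (MSE loss),
sigmoid for binary tasks (cross-entropy loss, stratified validation
split).  The head uses default initialization; fine-tuning updates **all**
layers, encoder included (a freeze switch exists).  One model is trained
per measurement feature.

**Training defaults.** Adam, learning rate 1e-3, batch 32, 200 epochs,
early stopping with patience 20 on validation loss, best-validation
checkpointing, all seeded and config-exposed.  Inputs are used as
log2(1+TPM) with no further scaling (a per-gene z-score switch exists but
defaults off).  The networks are plain NumPy (dense layers, three
activations, reverse-mode gradients) — small enough that a framework buys
nothing, and every arithmetic step is visible and deterministic.

## Evaluation protocol

Each (feature, model) pair is scored by five-fold cross-validation: four
folds train (neural models carve a further 10% validation split *from the
training portion*, avoiding leakage into the test fold), the held-out fold
is predicted, and MSE, RMSE and Spearman rank correlation (continuous) or
AUC and binary/macro F1 at a 0.5 threshold (binary) are recorded per fold.
Aggregates are means with t-based 95% confidence intervals — the same
formula serves fold-level and cross-feature aggregation, and both axes are
emitted since published tables are ambiguous about which is meant.
Features are partitioned into well predicted (RMSE strictly below the
first quartile) and poorly predicted (strictly above the third), with
linear-interpolation quantiles.  When a measurement type has more than
2000 features, a seeded uniform subsample of 2000 is evaluated.

Baselines: LASSO and elastic net with cross-validated regularization paths
(logistic counterparts for mutation), random forest (500 trees,
sqrt-features), PCA features + the same head architecture (200 components,
matching the bottleneck width so the comparison is dimensionally fair),
and `dnn_default` — the identical transfer architecture trained from
default initialization, so the only difference from the full method is the
encoder initialization.  All baselines consume the same KS-selected genes
(switchable).

## Screening post-analysis

Predicted drug-sensitivity scores below −2 (strict) call a compound active.
Per cancer group and drug, a 2×2 table (active/inactive × in/out-group)
feeds a two-sided Fisher exact test (probability-mass convention, matching
R); p-values are BH-adjusted across drugs within the group.  A drug-group
pair is *selectively effective* when the odds ratio exceeds 1 and q < 0.05;
drugs active in over 90% of all lines are *non-selective effective*
(both constants config-exposed).  The drug-within-group table construction
is an assumption — the alternative (group-within-drug) reading is not
distinguishable from the published description.

## The synthetic generator

`generate_domains` emulates exactly the structure the transfer method
assumes, at desk scale (defaults: 8 shared latent factors, 300 genes,
n_source = 2000, n_target = 250, 20 continuous + 5 binary features,
trains in minutes on one CPU):

- factors Z ~ N(0, I) per sample; expression = Z·Λᵀ + gene baseline means
  (uniform 1–8, resembling log2(1+TPM)) + N(0, 0.7²) noise; loadings Λ
  shared between domains up to the perturbations below;
- 30 designated genes get a +5 marginal-SD location shift in the target —
  the genes KS selection must reject;
- **domain differences**: every target gene gets a small mean offset
  (N(0, (0.3·SD)²)), target loadings carry a 30% relative jitter, and the
  target has 2 latent factors of its own that also drive the measurement
  targets.  These emulate, respectively, platform/level shifts,
  co-expression rewiring, and cell-line-specific programs (e.g., culture
  adaptation) absent from tumors.  Without them the non-shifted genes
  would be *identically* distributed in both domains, a source-only
  encoder would be optimal by construction, and the two-step-vs-variants
  comparison would be meaningless.  The perturbations are small enough
  that KS keeps the genes at the default sample sizes;
- continuous targets y = g(Z)·β + N(0, 0.5²) with g containing one squared
  factor term, so nonlinear models have something linear models cannot
  capture; the noiseless component is recorded so a per-feature noise
  ceiling (the Spearman between y and its noiseless part) is computable;
- binary targets are Bernoulli draws from a logistic transform of a latent
  score, recentered by bisection so the positive rate hits the configured
  20%;
- group labels (argmax over the first 3 latent factors) stand in for
  cancer types in the screening stage, so group-selective "drugs" exist by
  construction.

What the generator does **not** emulate: real marginal expression
distributions, batch effects, lineage structure, mutation co-occurrence.
Tests passing on this generator show the machinery is correct and the
transfer direction holds when its assumptions do; they do not certify
performance numbers on DepMap-scale data.

## The encoder ablation

`transcell.ablation.compare_encoder_variants` reruns the three-encoder
comparison per seed: equal epoch budgets for every variant (early stopping
disabled inside the ablation so "equal budget" is literal), reconstruction
loss measured on 50 held-out target samples, and downstream Spearman
measured with the encoder **frozen** and only the head trained (50
training samples, the rest test, averaged over 10 continuous features).
Freezing isolates representation quality — the property the ablation
varies; with unconstrained end-to-end fine-tuning at this scale every
initialization converges to statistically indistinguishable test scores
and the comparison measures optimizer noise.  Production models fine-tune
all layers.

Observed direction at the defaults (5 seeds): two-step < source-only <
target-only in reconstruction loss, and two-step > source-only >
target-only in downstream Spearman, with majority sign consistency per
seed pair; `scripts/acceptance.py` recomputes these numbers on every run.

## Numerical choices and edge cases

- KS p-values: asymptotic two-sided (`scipy.stats.ks_2samp`,
  `method="asymp"`); exact small-sample p-values are irrelevant at the
  targeted n.
- BH via `statsmodels`; Fisher exact via `scipy`; both are cross-checked
  in tests against independent step-up / hypergeometric-enumeration
  oracles, as are the AUC (pair enumeration) and quartile (sorting)
  implementations.
- Confidence intervals: mean ± t₀.₉₇₅,ₙ₋₁·s/√n; degenerate inputs (zero
  variance) collapse to the mean, n < 2 is an error.
- Spearman is undefined on constant vectors: unit-level calls raise; the
  CV driver records NaN for such folds and aggregates over the rest.
- Zero-epoch training budgets are strict no-ops (the epoch-0 evaluation is
  still logged, so histories are never empty).
- Weight files are HDF5 with a JSON header (dimensions, provenance, task,
  history); round-trips are bit-exact and loading into a mismatched
  declared architecture is an error.
- Expression files must be numerically complete; measurement tables accept
  "", "NA", "NaN" (case-insensitive) as missing.  Duplicate gene columns
  collapse to the first occurrence with a logged warning (how the source
  data handled duplicate symbols is undocumented); duplicate sample ids
  are an error.
- Orientation auto-detection: identifier-column header keywords first
  ("gene"/"symbol" vs "sample"/"cell"/...), then a gene-symbol regex vote
  over row and column ids; always overridable by flag.

## Known limitations

- Desk-scale problem sizes throughout (hundreds of samples, hundreds of
  genes, tens of epochs in the test suite); production-scale runs are a
  matter of config, not code, but are not exercised here.
- No automated hyperparameter search; the tuned per-type architectures of
  the production system are not public, so defaults are fixed and
  config-exposed.
- Gene identity is the exact symbol string; no alias resolution.
- The NumPy training loop is single-threaded; it is fast at the scales
  this package targets but is not a GPU framework.
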