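"""Synthetic paired-domain generator with the structure transfer assumes.

Both domains share a latent-factor model: per sample a d-dimensional
standard-normal factor vector Z, gene values Z @ L.T + baseline gene means
+ Gaussian noise, with the factor loadings L shared across domains — that
shared structure is what makes source pre-training transferable.  Two
kinds of domain difference are injected into the target:

* a designated subset of genes receives a large location shift
  (``shift_magnitude`` in units of the gene's marginal SD) — these are the
  genes the KS selection step must reject;
* every gene receives a small random mean offset
  (``domain_shift_sd``, also in marginal-SD units) and the target's factor
  loadings are mildly perturbed (``domain_loading_jitter``, relative to
  the loading scale), emulating the genuine tumor-versus-cell-line
  difference in both expression level and co-expression structure — small
  enough that KS keeps the genes, but large enough that an encoder
  trained on the source alone is miscalibrated on the target until
  fine-tuned;
* the target carries a few latent factors of its own
  (``n_target_only_factors``), absent from the source, that contribute to
  both expression and the measurement targets — the cell-line-specific
  programs a tumor-trained encoder has never seen and therefore
  compresses away.

Continuous measurement features are linear functions of the factors plus
one mild nonlinearity (a squared factor term) and Gaussian noise; binary
features are Bernoulli draws from a logistic transform of a latent score,
centered so the positive rate matches ``positive_rate``.  The generator
record ("truth") keeps loadings, coefficients, shifted-gene ids and the
factors so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import ExpressionMatrix, MeasurementTable


@dataclass
class SyntheticConfig:
    """Default desk-scale scenario: 8 factors, 300 genes, a large source
    domain (n=2000) and a small target domain (n=250), 30 genes shifted by
    5 SD, 20 continuous and 5 binary measurement features."""

    latent_dim: int = 8
    n_source: int = 2000
    n_target: int = 250
    n_genes: int = 300
    n_shifted_genes: int = 30
    shift_magnitude: float = 5.0
    domain_shift_sd: float = 0.3
    domain_loading_jitter: float = 0.3
    n_target_only_factors: int = 2
    loading_scale: float = 1.0
    noise_sd: float = 0.7
    target_noise_sd: float = 0.5
    n_continuous_features: int = 20
    n_binary_features: int = 5
    positive_rate: float = 0.2
    missing_rate: float = 0.0
    n_groups: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_shifted_genes > self.n_genes:
            raise ValueError("n_shifted_genes cannot exceed n_genes")
        for name in (
            "latent_dim",
            "n_source",
            "n_target",
            "n_genes",
            "n_continuous_features",
            "n_binary_features",
            "n_groups",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.positive_rate < 1.0:
            raise ValueError("positive_rate must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class SyntheticData:
    """Everything one simulated study produces."""

    source: ExpressionMatrix
    target: ExpressionMatrix
    measurements: MeasurementTable  # continuous targets for the target domain
    mutations: MeasurementTable  # binary targets for the target domain
    group_labels: list  # one cancer-group label per target sample
    truth: dict


def _expression(Z, loadings, gene_means, noise_sd, rng):
    return Z @ loadings.T + gene_means + rng.normal(0.0, noise_sd, (Z.shape[0], len(gene_means)))


def _solve_logistic_offset(scores: np.ndarray, rate: float) -> float:
    """Bisection for c so that mean(sigmoid(scores + c)) == rate."""
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if np.mean(1.0 / (1.0 + np.exp(-(scores + mid)))) < rate:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def generate_domains(config: SyntheticConfig | None = None, **overrides) -> SyntheticData:
    """Draw one paired source/target study from the latent-factor model."""
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        config = SyntheticConfig(**{**asdict(config), **overrides})
    c = config
    rng = np.random.default_rng(c.seed)

    gene_ids = [f"G{i:04d}" for i in range(c.n_genes)]
    loading_sd = c.loading_scale / np.sqrt(c.latent_dim)
    loadings = rng.normal(0.0, loading_sd, (c.n_genes, c.latent_dim))
    # target loadings: jittered shared factors plus target-only factors
    extra = c.n_target_only_factors
    target_loadings = np.column_stack(
        [
            loadings + c.domain_loading_jitter * rng.normal(0.0, loading_sd, loadings.shape),
            rng.normal(0.0, loading_sd, (c.n_genes, extra)),
        ]
    )
    gene_means = rng.uniform(1.0, 8.0, c.n_genes)
    marginal_sd = np.sqrt((loadings**2).sum(axis=1) + c.noise_sd**2)

    shifted_idx = np.sort(rng.choice(c.n_genes, size=c.n_shifted_genes, replace=False))
    shifted_genes = [gene_ids[i] for i in shifted_idx]
    domain_offsets = rng.normal(0.0, c.domain_shift_sd, c.n_genes) * marginal_sd

    Z_source = rng.standard_normal((c.n_source, c.latent_dim))
    Z_target = rng.standard_normal((c.n_target, c.latent_dim + extra))

    X_source = _expression(Z_source, loadings, gene_means, c.noise_sd, rng)
    X_target = _expression(Z_target, target_loadings, gene_means, c.noise_sd, rng)
    X_target += domain_offsets
    X_target[:, shifted_idx] += c.shift_magnitude * marginal_sd[shifted_idx]

    source = ExpressionMatrix(
        [f"SRC{i:05d}" for i in range(c.n_source)], gene_ids, X_source
    )
    target = ExpressionMatrix(
        [f"TGT{i:05d}" for i in range(c.n_target)], gene_ids, X_target
    )

    # continuous targets: linear in the factors plus one squared-factor term
    g = np.column_stack([Z_target, Z_target[:, 0] ** 2 - 1.0])
    beta = rng.standard_normal((g.shape[1], c.n_continuous_features))
    beta /= np.linalg.norm(beta, axis=0, keepdims=True)  # unit signal scale
    y_clean = g @ beta
    y = y_clean + rng.normal(0.0, c.target_noise_sd, y_clean.shape)
    if c.missing_rate > 0:
        y[rng.random(y.shape) < c.missing_rate] = np.nan
    cont_ids = [f"F{j:03d}" for j in range(c.n_continuous_features)]
    measurements = MeasurementTable(
        sample_ids=list(target.sample_ids),
        feature_ids=cont_ids,
        values=y,
        measurement_type="metabolite",
    )

    # binary targets: logistic transform of a latent score, thinned to the rate
    w = rng.standard_normal((Z_target.shape[1], c.n_binary_features))
    w /= np.linalg.norm(w, axis=0, keepdims=True)
    latent_score = Z_target @ w * 2.0  # steepness: clearly separable classes
    probs = np.empty_like(latent_score)
    for j in range(c.n_binary_features):
        offset = _solve_logistic_offset(latent_score[:, j], c.positive_rate)
        probs[:, j] = 1.0 / (1.0 + np.exp(-(latent_score[:, j] + offset)))
    labels = (rng.random(probs.shape) < probs).astype(float)
    if c.missing_rate > 0:
        labels[rng.random(labels.shape) < c.missing_rate] = np.nan
    bin_ids = [f"MUT{j:03d}" for j in range(c.n_binary_features)]
    mutations = MeasurementTable(
        sample_ids=list(target.sample_ids),
        feature_ids=bin_ids,
        values=labels,
        measurement_type="mutation",
    )

    # cancer-style groups: argmax over the first n_groups latent factors,
    # so groups genuinely differ in their measurement profiles
    k = min(c.n_groups, c.latent_dim)
    group_labels = [f"group{int(i)}" for i in np.argmax(Z_target[:, :k], axis=1)]

    truth = {
        "config": asdict(c),
        "loadings": loadings,
        "target_loadings": target_loadings,
        "gene_means": gene_means,
        "marginal_sd": marginal_sd,
        "domain_offsets": domain_offsets,
        "shifted_genes": shifted_genes,
        "Z_source": Z_source,
        "Z_target": Z_target,
        "beta": beta,
        "binary_weights": w,
        "y_clean": y_clean,
        "continuous_feature_ids": cont_ids,
        "binary_feature_ids": bin_ids,
    }
    return SyntheticData(
        source=source,
        target=target,
        measurements=measurements,
        mutations=mutations,
        group_labels=group_labels,
        truth=truth,
    )


def noise_ceiling(truth: dict, feature_id: str) -> float:
    """Spearman correlation between a continuous target's noisy values and
    its noiseless component: the best any predictor can do."""
    from .evaluation import spearman

    j = truth["continuous_feature_ids"].index(feature_id)
    clean = truth["y_clean"][:, j]
    cfg = truth["config"]
    rng = np.random.default_rng(cfg["seed"] + 104729)  # independent noise draw
    noisy = clean + rng.normal(0.0, cfg["target_noise_sd"], clean.shape)
    return spearman(noisy, clean)


def truth_recovery_report(truth: dict, selection=None, model_metrics: dict | None = None) -> dict:
    """Score a feature-selection result (and optionally model metrics)
    against the generator record.

    Exclusion recall = fraction of truly shifted genes the selection
    excluded; exclusion precision = fraction of excluded genes that were
    truly shifted.  Model Spearman values are reported next to each
    feature's noise ceiling.
    """
    report: dict = {}
    if selection is not None:
        known = set(selection.gene_ids)
        shifted = set(truth["shifted_genes"])
        if not shifted <= known:
            raise ValueError("selection gene set does not cover the shifted genes")
        excluded = known - set(selection.selected)
        hit = len(excluded & shifted)
        report["exclusion_recall"] = hit / len(shifted) if shifted else 1.0
        report["exclusion_precision"] = hit / len(excluded) if excluded else 1.0
        report["n_excluded"] = len(excluded)
    if model_metrics:
        per_feature = {}
        for fid, rho in model_metrics.items():
            per_feature[fid] = {
                "spearman": rho,
                "noise_ceiling": noise_ceiling(truth, fid),
            }
        report["features"] = per_feature
    return report
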