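"""Cross-domain feature selection by per-gene two-sample KS tests.

Transfer from tumors to cell lines degrades when the domains disagree
(negative transfer), so only genes whose expression distribution is
similar in both domains are kept: a two-sample Kolmogorov-Smirnov test
runs per shared gene, p-values are multiplicity-adjusted, and the k genes
with the LARGEST adjusted p (most similar distributions) are selected.
Ties — common because many adjusted p-values saturate at 1 — break by
smaller KS statistic, then lexicographic gene id, so the ranking is
deterministic across platforms.

Also hosts the selectors used by the baseline model suite (LASSO, elastic
net, random-forest importance, PCA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNetCV, LassoCV
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

logger = logging.getLogger("transcell")


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample KS statistic D = sup_t |F_x(t) - F_y(t)| and its
    asymptotic two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Multiplicity adjustment; Benjamini-Hochberg step-up by default,
    Bonferroni available as a config hook."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


@dataclass
class FeatureSelectionResult:
    """Per-gene KS statistics and the ordered selected-gene list."""

    gene_ids: list
    ks_statistic: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    selected: list
    k: int

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready table: gene_id, D, p_raw, p_adjusted, rank, selected."""
        order = rank_gene_similarity(self.gene_ids, self.ks_statistic, self.p_adjusted)
        rank = {g: r + 1 for r, g in enumerate(order)}
        sel = set(self.selected)
        df = pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "D": self.ks_statistic,
                "p_raw": self.p_raw,
                "p_adjusted": self.p_adjusted,
                "rank": [rank[g] for g in self.gene_ids],
                "selected": [int(g in sel) for g in self.gene_ids],
            }
        )
        return df.sort_values("rank").reset_index(drop=True)


def rank_gene_similarity(gene_ids, ks_statistic, p_adjusted) -> list:
    """Most-similar-first gene order: descending adjusted p, then ascending
    D, then lexicographic gene id."""
    rows = sorted(
        zip(gene_ids, ks_statistic, p_adjusted),
        key=lambda r: (-r[2], r[1], r[0]),
    )
    return [g for g, _, _ in rows]


def select_similar_genes(
    source: ExpressionMatrix,
    target: ExpressionMatrix,
    k: int,
    method: str = "bh",
) -> FeatureSelectionResult:
    """Run the per-gene KS test over the shared genes of two domains and
    keep the k most similar (largest adjusted p)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    shared = sorted(set(source.gene_ids) & set(target.gene_ids))
    if not shared:
        raise ValueError("source and target share no genes")
    if k > len(shared):
        logger.warning(
            "requested k=%d exceeds %d shared genes; selecting all", k, len(shared)
        )
        k = len(shared)

    src = source.to_frame()
    tgt = target.to_frame()
    D = np.empty(len(shared))
    p_raw = np.empty(len(shared))
    for i, g in enumerate(shared):
        D[i], p_raw[i] = ks_two_sample(src[g].to_numpy(), tgt[g].to_numpy())
    p_adj = adjust_pvalues(p_raw, method=method)
    order = rank_gene_similarity(shared, D, p_adj)
    return FeatureSelectionResult(
        gene_ids=shared,
        ks_statistic=D,
        p_raw=p_raw,
        p_adjusted=p_adj,
        selected=order[:k],
        k=k,
    )


class KSGeneSelector(BaseEstimator):
    """Transformer wrapping :func:`select_similar_genes`.

    fit(source, target) computes the per-gene KS ranking; transform
    restricts an :class:`ExpressionMatrix` (or DataFrame) to the selected
    genes in ranked order.
    """

    def __init__(self, k: int = 5000, method: str = "bh"):
        self.k = k
        self.method = method

    @staticmethod
    def _as_matrix(X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            return ExpressionMatrix.from_frame(X)
        raise TypeError("expected an ExpressionMatrix or DataFrame with gene columns")

    def fit(self, source, target):
        self.result_ = select_similar_genes(
            self._as_matrix(source), self._as_matrix(target), self.k, self.method
        )
        self.selected_genes_ = list(self.result_.selected)
        return self

    def transform(self, X):
        if not hasattr(self, "selected_genes_"):
            raise RuntimeError("KSGeneSelector is not fitted")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.selected_genes_]
        return self._as_matrix(X).subset_genes(self.selected_genes_)

    def fit_transform(self, source, target):
        return self.fit(source, target).transform(target)


def baseline_feature_select(
    X,
    y=None,
    method: str = "lasso",
    k: int | None = None,
    n_components: int | None = None,
    seed: int = 0,
):
    """Selectors used by the baseline suite.

    lasso / en return the nonzero-coefficient column indices of a
    cross-validated fit; rf returns the top-k columns by impurity
    importance; pca returns a fitted orthogonal projection.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if method == "pca":
        if n_components is None:
            n_components = min(X.shape)
        return PCA(n_components=n_components, random_state=seed).fit(X)

    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise ValueError("constant target: supervised selection undefined")
    if method == "lasso":
        model = LassoCV(cv=5, random_state=seed, max_iter=5000).fit(X, y)
        return list(np.flatnonzero(model.coef_))
    if method == "en":
        model = ElasticNetCV(cv=5, l1_ratio=0.5, random_state=seed, max_iter=5000).fit(X, y)
        return list(np.flatnonzero(model.coef_))
    if method == "rf":
        if not k or k < 1:
            raise ValueError("rf selection requires k >= 1")
        rf = RandomForestRegressor(n_estimators=200, random_state=seed, n_jobs=1).fit(X, y)
        return list(np.argsort(rf.feature_importances_)[::-1][:k])
    raise ValueError(f"unknown selection method {method!r}")
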