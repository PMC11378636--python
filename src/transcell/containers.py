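"""Core data containers shared by every pipeline stage.

An :class:`ExpressionMatrix` holds log2(1+TPM) expression for one domain in
the canonical samples-in-rows orientation.  A :class:`MeasurementTable`
holds one of the six measurement types (metabolite, protein, CNV, gene
effect, drug sensitivity, mutation); mutation is the only binary type and
the only one allowed to carry missing entries alongside the continuous
types.  :func:`align_task` intersects the two on sample ids and produces
the per-feature supervised task consumed by the models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MEASUREMENT_TYPES = (
    "metabolite",
    "protein",
    "cnv",
    "gene_effect",
    "drug_sensitivity",
    "mutation",
)

CONTINUOUS = "continuous"
BINARY = "binary"


def _check_unique(ids, what: str) -> list:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what} identifiers: {sorted(set(dups))[:10]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Samples x genes matrix of log2(1+TPM) values.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row.
    gene_ids : list of str
        Unique gene symbols, one per column.  Gene identity is the bare
        symbol string, matched exactly and case-sensitively.
    values : ndarray of shape (n_samples, n_genes)
        Complete (no missing entries), finite expression values.
    """

    sample_ids: list
    gene_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        """Restrict to ``gene_ids`` in the given order."""
        missing = [g for g in gene_ids if g not in set(self.gene_ids)]
        if missing:
            raise KeyError(f"unknown genes: {missing[:10]}")
        col = {g: j for j, g in enumerate(self.gene_ids)}
        idx = [col[g] for g in gene_ids]
        return ExpressionMatrix(self.sample_ids, list(gene_ids), self.values[:, idx])


@dataclass
class MeasurementTable:
    """Samples x features table for one measurement type.

    Missing entries are represented by NaN.  ``value_kind`` is "binary"
    exactly when ``measurement_type`` is "mutation"; binary entries are
    0, 1, or missing.
    """

    sample_ids: list
    feature_ids: list
    values: np.ndarray
    measurement_type: str = "metabolite"
    value_kind: str | None = None

    def __post_init__(self):
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("values shape does not match id lists")
        if self.measurement_type not in MEASUREMENT_TYPES:
            raise ValueError(
                f"measurement_type must be one of {MEASUREMENT_TYPES}, "
                f"got {self.measurement_type!r}"
            )
        expected_kind = BINARY if self.measurement_type == "mutation" else CONTINUOUS
        if self.value_kind is None:
            self.value_kind = expected_kind
        elif self.value_kind != expected_kind:
            raise ValueError(
                f"value_kind {self.value_kind!r} inconsistent with "
                f"measurement_type {self.measurement_type!r}"
            )
        if self.value_kind == BINARY:
            observed = self.values[~np.isnan(self.values)]
            if observed.size and not np.isin(observed, (0.0, 1.0)).all():
                raise ValueError("binary measurement values must be 0, 1 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class AlignedTask:
    """One supervised task: selected-gene expression vs one target feature.

    Samples are the intersection of the expression and measurement sample
    sets with missing targets dropped, mirroring the per-feature sample
    attrition of real cell-line panels ("the number of cell lines varies
    across data types").
    """

    X: np.ndarray
    y: np.ndarray
    sample_ids: list
    gene_ids: list
    feature_id: str
    value_kind: str = CONTINUOUS

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.y.ndim != 1:
            raise ValueError("X must be 2-D and y 1-D")
        if len(self.y) != self.X.shape[0] or len(self.y) != len(self.sample_ids):
            raise ValueError("inconsistent sample counts")
        if len(self.y) == 0:
            raise ValueError("aligned task has no samples")
        if np.isnan(self.y).any():
            raise ValueError("aligned target contains missing values")

    @property
    def n_samples(self) -> int:
        return len(self.y)


def align_task(
    expr: ExpressionMatrix,
    meas: MeasurementTable,
    feature_id: str,
    selected_genes=None,
) -> AlignedTask:
    """Build the supervised task for one measurement feature.

    Intersects sample ids of ``expr`` and ``meas`` (expression order kept),
    drops samples whose target value is missing, and restricts the design
    matrix to ``selected_genes`` in the given order (all genes when None).
    """
    if feature_id not in meas.feature_ids:
        raise KeyError(f"feature {feature_id!r} not in measurement table")
    if selected_genes is None:
        selected_genes = list(expr.gene_ids)
    else:
        selected_genes = list(selected_genes)
        unknown = sorted(set(selected_genes) - set(expr.gene_ids))
        if unknown:
            raise KeyError(f"selected genes missing from expression matrix: {unknown[:10]}")

    meas_rows = {s: i for i, s in enumerate(meas.sample_ids)}
    shared = [s for s in expr.sample_ids if s in meas_rows]
    if not shared:
        raise ValueError("expression and measurement tables share no samples")

    fcol = meas.feature_ids.index(feature_id)
    y_all = np.array([meas.values[meas_rows[s], fcol] for s in shared])
    keep = ~np.isnan(y_all)
    kept = [s for s, k in zip(shared, keep) if k]
    if not kept:
        raise ValueError(f"all shared samples have missing target for {feature_id!r}")

    expr_rows = {s: i for i, s in enumerate(expr.sample_ids)}
    col = {g: j for j, g in enumerate(expr.gene_ids)}
    gidx = [col[g] for g in selected_genes]
    X = expr.values[np.array([expr_rows[s] for s in kept])][:, gidx]
    return AlignedTask(
        X=X,
        y=y_all[keep],
        sample_ids=kept,
        gene_ids=selected_genes,
        feature_id=feature_id,
        value_kind=meas.value_kind,
    )
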