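"""Five-fold cross-validation protocol, metrics, and aggregation.

Each measurement feature is evaluated by five-fold CV: four folds train
the model (neural models carve a further 10% validation split from the
training portion), the held-out fold is predicted, and MSE / RMSE /
Spearman rank correlation (or AUC / F1 for binary tasks) are computed per
fold and aggregated as mean with a t-based 95% confidence interval.
Features are then partitioned into well predicted (RMSE below the first
quartile) and poorly predicted (RMSE above the third quartile).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .containers import AlignedTask


def kfold_split(sample_ids, k: int = 5, seed: int = 0, stratify=None) -> dict:
    """Seeded k-fold assignment (sample id -> fold index), near-equal fold
    sizes; stratified when binary labels are supplied."""
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    idx = np.arange(n)
    if stratify is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(idx, np.asarray(stratify))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(idx)
    assignment = {}
    for fold, (_, test_idx) in enumerate(splits):
        for i in test_idx:
            assignment[sample_ids[i]] = fold
    return assignment


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _check_pair(y, y_hat):
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if len(y) != len(y_hat):
        raise ValueError("length mismatch")
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    return y, y_hat


def mse(y, y_hat) -> float:
    y, y_hat = _check_pair(y, y_hat)
    return float(np.mean((y - y_hat) ** 2))


def rmse(y, y_hat) -> float:
    return float(np.sqrt(mse(y, y_hat)))


def spearman(y, y_hat) -> float:
    """Spearman rank correlation with average ranks for ties; undefined
    (error) for constant inputs."""
    y, y_hat = _check_pair(y, y_hat)
    if np.ptp(y) == 0 or np.ptp(y_hat) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    return float(stats.spearmanr(y, y_hat).statistic)


def auc(y, scores) -> float:
    """Probability a positive outranks a negative (ties count one half)."""
    y, scores = _check_pair(y, scores)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, scores))


def f1(y, y_hat_class, averaging: str = "binary") -> float:
    y, y_hat_class = _check_pair(y, y_hat_class)
    if averaging not in ("binary", "macro"):
        raise ValueError("averaging must be 'binary' or 'macro'")
    return float(f1_score(y.astype(int), y_hat_class.astype(int), average=averaging))


def aggregate_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Mean with t-based confidence interval: mean +/- t_{(1+level)/2, n-1} * s/sqrt(n)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    m = float(np.mean(values))
    s = float(np.std(values, ddof=1))
    half = stats.t.ppf((1 + level) / 2, df=n - 1) * s / np.sqrt(n)
    return m, m - half, m + half


# ---------------------------------------------------------------------------
# cross-validation driver
# ---------------------------------------------------------------------------


@dataclass
class CVEvaluation:
    """Per-fold and aggregate metrics for one (feature, method) pair."""

    feature_id: str
    method: str
    per_fold: list
    aggregate: dict  # metric -> (mean, lower, upper)
    fold_assignments: dict
    seed: int

    def to_rows(self) -> pd.DataFrame:
        rows = [
            {"feature_id": self.feature_id, "method": self.method, "fold": i, "metric": m, "value": v}
            for i, fold in enumerate(self.per_fold)
            for m, v in fold.items()
        ]
        return pd.DataFrame(rows)


def _classification_scores(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))[:, 1]
    return np.asarray(model.predict(X), dtype=float).ravel()


def run_cv(task: AlignedTask, model_factory, k: int = 5, seed: int = 0) -> CVEvaluation:
    """Five-fold CV of one model family on one aligned task.

    ``model_factory()`` must return a fresh unfitted model exposing
    fit/predict (predict_proba used for binary tasks when present).
    Spearman is recorded as NaN on folds where either vector is constant
    and excluded from the aggregate.
    """
    binary = task.value_kind == "binary"
    assignment = kfold_split(
        task.sample_ids, k=k, seed=seed, stratify=task.y if binary else None
    )
    folds = np.array([assignment[s] for s in task.sample_ids])
    per_fold = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        model = model_factory()
        try:
            model.fit(task.X[train], task.y[train])
        except Exception as exc:  # annotate with the fold index
            raise RuntimeError(f"model fit failed on fold {fold}: {exc}") from exc
        if binary:
            scores = _classification_scores(model, task.X[test])
            classes = (scores >= 0.5).astype(int)
            per_fold.append(
                {
                    "auc": auc(task.y[test], scores),
                    "f1_binary": f1(task.y[test], classes, "binary"),
                    "f1_macro": f1(task.y[test], classes, "macro"),
                }
            )
        else:
            y_hat = np.asarray(model.predict(task.X[test]), dtype=float).ravel()
            fold_mse = mse(task.y[test], y_hat)
            try:
                rho = spearman(task.y[test], y_hat)
            except ValueError:
                rho = float("nan")
            per_fold.append({"mse": fold_mse, "rmse": float(np.sqrt(fold_mse)), "spearman": rho})

    aggregate = {}
    for metric in per_fold[0]:
        values = np.array([fold[metric] for fold in per_fold], dtype=float)
        finite = values[np.isfinite(values)]
        if len(finite) >= 2:
            aggregate[metric] = aggregate_ci(finite)
        elif len(finite) == 1:
            aggregate[metric] = (float(finite[0]),) * 3
        else:
            aggregate[metric] = (float("nan"),) * 3
    return CVEvaluation(
        feature_id=task.feature_id,
        method=getattr(model_factory, "method_name", "model"),
        per_fold=per_fold,
        aggregate=aggregate,
        fold_assignments=assignment,
        seed=seed,
    )


def quartile_partition(per_feature_rmse: dict) -> dict:
    """Well predicted: RMSE strictly below Q1; poorly predicted: strictly
    above Q3 (linear-interpolation quartiles)."""
    if len(per_feature_rmse) < 4:
        raise ValueError("need at least 4 features to form quartiles")
    values = np.array(list(per_feature_rmse.values()), dtype=float)
    q1, q3 = np.percentile(values, [25, 75])
    return {
        "well": {f for f, v in per_feature_rmse.items() if v < q1},
        "poor": {f for f, v in per_feature_rmse.items() if v > q3},
        "q1": float(q1),
        "q3": float(q3),
    }


def subsample_features(feature_ids, cap: int = 2000, seed: int = 0) -> list:
    """Seeded uniform subsample without replacement when the feature count
    exceeds the cap (the scale-up protocol); identity otherwise."""
    feature_ids = list(feature_ids)
    if len(feature_ids) <= cap:
        return feature_ids
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(feature_ids), size=cap, replace=False)
    return [feature_ids[i] for i in sorted(idx)]


def build_benchmark_table(evaluations: list, quartile_method: str | None = None) -> pd.DataFrame:
    """Aggregate rows across features x methods, with well/poor quartile
    labels for the designated scale-up method."""
    rows = []
    for ev in evaluations:
        for metric, (m, lo, hi) in ev.aggregate.items():
            rows.append(
                {
                    "feature_id": ev.feature_id,
                    "method": ev.method,
                    "metric": metric,
                    "mean": m,
                    "ci_lower": lo,
                    "ci_upper": hi,
                }
            )
    table = pd.DataFrame(rows)
    table["partition"] = ""
    if quartile_method is not None:
        sub = table[(table.method == quartile_method) & (table.metric == "rmse")]
        if len(sub) >= 4:
            parts = quartile_partition(dict(zip(sub.feature_id, sub["mean"])))
            label = {f: "well" for f in parts["well"]}
            label.update({f: "poor" for f in parts["poor"]})
            mask = table.method == quartile_method
            table.loc[mask, "partition"] = [
                label.get(f, "") for f in table.loc[mask, "feature_id"]
            ]
    return table
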