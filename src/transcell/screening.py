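"""Drug-screening post-analysis: active-compound calling and selectivity.

Predicted drug-sensitivity scores are thresholded (score < -2 by default,
strict inequality) into active/inactive calls.  Per cancer group, each
drug gets a 2x2 table (active/inactive x in-group/out-group) and a
two-sided Fisher exact test; p-values are BH-adjusted across drugs within
the group.  A drug-group pair is called selectively effective when the
odds ratio exceeds 1 and the adjusted q-value passes the cutoff; drugs
active in more than 90% of all lines are "non-selective effective".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .feature_selection import adjust_pvalues

ACTIVE_THRESHOLD = -2.0


@dataclass
class ScreenMatrix:
    """Predicted sensitivity scores for cell lines (with group labels) x drugs."""

    cell_line_ids: list
    group_labels: list
    drug_ids: list
    scores: np.ndarray
    threshold: float = ACTIVE_THRESHOLD

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.cell_line_ids), len(self.drug_ids)):
            raise ValueError("scores shape does not match id lists")
        if len(self.group_labels) != len(self.cell_line_ids):
            raise ValueError("one group label per cell line required")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")

    @property
    def active(self) -> np.ndarray:
        return call_active(self.scores, self.threshold)

    @property
    def groups(self) -> list:
        seen = []
        for g in self.group_labels:
            if g not in seen:
                seen.append(g)
        return seen


def call_active(scores, threshold: float = ACTIVE_THRESHOLD) -> np.ndarray:
    """Strict less-than call: a score exactly at the threshold is inactive."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return scores < threshold


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns (odds_ratio, p).  The two-sided p sums the probabilities of
    all tables with the observed margins whose conditional probability
    does not exceed the observed table's (the probability-mass method,
    matching R's convention).  Odds ratio is the sample ad/bc with the
    usual 0 and infinity conventions on zero margins.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.number):
        raise ValueError("counts must be non-negative")
    if t.sum() <= 0:
        raise ValueError("grand total must be positive")
    res = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel().astype(float)
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(res.pvalue)


@dataclass
class SelectivityResult:
    """Per-drug selectivity within one cancer group."""

    group: str
    table: pd.DataFrame  # drug_id, a, b, c, d, odds_ratio, p, q, selective

    def selective_drugs(self) -> list:
        return list(self.table.loc[self.table.selective, "drug_id"])


def drug_selectivity(
    screen: ScreenMatrix,
    group: str,
    q_cutoff: float = 0.05,
    effective_fraction: float = 0.9,
) -> SelectivityResult:
    """Fisher-exact selectivity of every drug for one cancer group.

    The 2x2 table per drug is [[active & in-group, active & out-group],
    [inactive & in-group, inactive & out-group]]; p-values are BH-adjusted
    across drugs within the group.  ``selective`` requires odds ratio > 1
    and q below the cutoff.  Drugs active in more than
    ``effective_fraction`` of ALL lines are flagged non-selective
    effective instead.
    """
    labels = np.asarray(screen.group_labels)
    if group not in labels:
        raise ValueError(f"group {group!r} not present")
    if len(set(screen.group_labels)) < 2:
        raise ValueError("selectivity requires at least 2 groups")
    active = screen.active
    in_group = labels == group
    rows = []
    for j, drug in enumerate(screen.drug_ids):
        act = active[:, j]
        a = int(np.sum(act & in_group))
        b = int(np.sum(act & ~in_group))
        c = int(np.sum(~act & in_group))
        d = int(np.sum(~act & ~in_group))
        odds, p = fisher_exact([[a, b], [c, d]])
        rows.append(
            {
                "drug_id": drug,
                "active_in": a,
                "active_out": b,
                "inactive_in": c,
                "inactive_out": d,
                "odds_ratio": odds,
                "p": p,
                "active_fraction": float(act.mean()),
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = adjust_pvalues(table["p"].to_numpy())
    table["non_selective_effective"] = table.active_fraction > effective_fraction
    table["selective"] = (
        (table.odds_ratio > 1) & (table.q < q_cutoff) & ~table.non_selective_effective
    )
    return SelectivityResult(group=group, table=table)


def classify_drugs(screen: ScreenMatrix, effective_fraction: float = 0.9) -> pd.DataFrame:
    """Coarse drug classes over the whole panel: non-selective effective
    (active in > fraction of lines), ineffective (inactive in > fraction),
    or mixed."""
    active = screen.active
    frac = active.mean(axis=0)
    label = np.where(
        frac > effective_fraction,
        "non_selective_effective",
        np.where(1.0 - frac > effective_fraction, "ineffective", "mixed"),
    )
    return pd.DataFrame(
        {"drug_id": screen.drug_ids, "active_fraction": frac, "class": label}
    )
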