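"""Marker-panel scoring: studentization, wanted/unwanted summary scores,
condition ranking and ranking/profile correlations.

Replicate samples are first collapsed to per-condition means, then each
gene is studentized across conditions (z-score with the n-1 sample sd);
a condition's wanted (unwanted) score is the mean of the studentized
values over the wanted (unwanted) marker set.  A gene with zero sd
across conditions maps to an all-zero row and is flagged degenerate
rather than producing NaNs, so set means stay defined.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ExpressionMatrix
from .design import GenePanel

__all__ = [
    "StudentizedMatrix", "studentize", "marker_scores",
    "rank_correlation", "profile_correlation", "MarkerScorer",
]


@dataclasses.dataclass
class StudentizedMatrix:
    """Per-gene z-scores across conditions, with the audit trail."""

    values: pd.DataFrame          # genes x condition ids
    gene_mean: pd.Series
    gene_sd: pd.Series
    degenerate: pd.Series         # True where sd == 0 (row forced to 0)
    day: int | None = None


def studentize(expr: ExpressionMatrix, day: int | None = None,
               conditions: list[int] | None = None) -> StudentizedMatrix:
    """Collapse replicates to condition means, then z-score each gene.

    ``day=None`` pools all days, treating each (condition, day) pair as
    a unit; an integer restricts to that day's samples.
    """
    samples = expr.samples
    mask = pd.Series(True, index=samples.index)
    if day is not None:
        mask &= samples["day"] == day
    if conditions is not None:
        mask &= samples["condition_id"].isin(conditions)
    sub = expr.values.loc[:, mask[mask].index]
    if day is None:
        key = pd.Series(
            list(zip(samples.loc[mask, "condition_id"],
                     samples.loc[mask, "day"])),
            index=sub.columns)
    else:
        key = samples.loc[mask, "condition_id"]
    collapsed = sub.T.groupby(key).mean().T
    if collapsed.shape[1] < 2:
        raise ValueError(
            "studentization needs at least 2 conditions, got "
            f"{collapsed.shape[1]}")
    mean = collapsed.mean(axis=1)
    sd = collapsed.std(axis=1, ddof=1)
    degenerate = sd == 0
    z = collapsed.sub(mean, axis=0).div(sd.where(~degenerate, 1.0), axis=0)
    z[degenerate] = 0.0
    return StudentizedMatrix(values=z, gene_mean=mean, gene_sd=sd,
                             degenerate=degenerate, day=day)


def marker_scores(z: StudentizedMatrix, panel: GenePanel) -> pd.DataFrame:
    """Wanted/unwanted summary scores per condition, with ranks.

    Ranking is descending by wanted score; ties break by ascending
    unwanted score, then condition id.
    """
    table = pd.DataFrame(index=z.values.columns)
    for name in ("wanted", "unwanted"):
        members = [g for g in panel.marker_set(name) if g in z.values.index]
        if not members:
            raise ValueError(f"marker set {name!r} absent from the matrix")
        table[f"{name}_score"] = z.values.loc[members].mean(axis=0)
    # final tie-break on condition id: pre-sort by index, mergesort is stable
    order = table.sort_index().sort_values(
        by=["wanted_score", "unwanted_score"],
        ascending=[False, True], kind="mergesort")
    table["rank"] = pd.Series(range(1, len(table) + 1), index=order.index)
    if z.day is not None:
        table["day"] = z.day
    return table


def _exact_spearman_p(rho_obs: float, n: int) -> float:
    """Two-sided exact permutation p for Spearman rho (n <= 9)."""
    base = np.arange(1, n + 1, dtype=float)
    denom = float(((base - base.mean()) ** 2).sum())
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = base[list(perm)]
        rho = float(((base - base.mean()) * (r - r.mean())).sum()) / denom
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def rank_correlation(day1: pd.DataFrame, day7: pd.DataFrame) -> dict:
    """Spearman correlation between two condition rankings.

    Computed on the wanted scores with average-rank ties; the p-value is
    the t approximation, or the exact permutation distribution for
    n <= 9.
    """
    a = day1["wanted_score"]
    b = day7["wanted_score"]
    if set(a.index) != set(b.index):
        raise ValueError("condition sets of the two tables differ")
    b = b.loc[a.index]
    n = len(a)
    rho, p = stats.spearmanr(a, b)
    if n <= 9:
        p = _exact_spearman_p(float(rho), n)
    return {"rho": float(rho), "p": float(p), "n": n}


def profile_correlation(a: pd.Series, b: pd.Series) -> dict:
    """Pearson correlation between two paired log-scale profiles
    (e.g. lysate vs purified RNA of the same sample)."""
    if set(a.index) != set(b.index):
        raise ValueError("profiles are on different gene universes")
    b = b.loc[a.index]
    if len(a) < 3:
        raise ValueError("need at least 3 genes")
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        raise ValueError("zero variance in a profile")
    r, p = stats.pearsonr(a, b)
    return {"r": float(r), "r2": float(r) ** 2, "p": float(p)}


class MarkerScorer(BaseEstimator, TransformerMixin):
    """Estimator wrapper: studentize a screen and emit marker scores."""

    def __init__(self, day: int | None = None,
                 conditions: list[int] | None = None):
        self.day = day
        self.conditions = conditions

    def fit(self, X: ExpressionMatrix, y=None):
        self.studentized_ = studentize(X, self.day, self.conditions)
        return self

    def transform(self, X: ExpressionMatrix, panel: GenePanel = None
                  ) -> pd.DataFrame:
        if panel is None:
            raise ValueError("transform requires the gene panel")
        z = studentize(X, self.day, self.conditions)
        return marker_scores(z, panel)
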