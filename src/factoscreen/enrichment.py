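"""Competitive gene-set enrichment ranking of conditions, and PCA.

Enrichment is a competitive mean-rank test: for each condition the
per-gene moderated t statistics of its contrast against the baseline
medium are compared between the marker set and all other genes with a
Wilcoxon rank-sum test (directional for up/down).  Being rank-based the
p-value is invariant to any strictly monotone transform of the
statistics.  FDRs are Benjamini-Hochberg across the non-baseline
conditions within each marker set, and a condition is flagged when it
is enriched for the wanted set but not for the unwanted set.

PCA is a gene-centered SVD of the normalized expression with a fixed
sign convention (the gene with the largest absolute loading of each
component is made positive).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix
from .design import ConditionRegistry, GenePanel
from .diffexp import (
    BASELINE_CONDITION, ContrastSpec, bh_adjust, contrast_de,
    fit_genewise_models,
)

__all__ = [
    "gene_set_test", "enrichment_table", "PCAResult", "pca",
    "heatmap_order", "ScreenPCA",
]


def gene_set_test(stats_per_gene: pd.Series, gene_set, direction: str = "up",
                  ) -> dict:
    """Competitive mean-rank test of a gene set.

    Wilcoxon rank-sum of the set's statistics against all other genes';
    ``direction='up'`` tests for larger statistics in the set,
    ``'down'`` for smaller, ``'either'`` is two-sided.  The statistic
    reported is the rank-biserial AUC (fraction of set-vs-rest pairs
    where the set gene's statistic is larger).
    """
    in_set = stats_per_gene.index.isin(set(gene_set))
    if not in_set.any():
        raise ValueError("gene set does not intersect the statistic universe")
    x = stats_per_gene[in_set].to_numpy()
    rest = stats_per_gene[~in_set].to_numpy()
    if len(rest) == 0:
        return {"statistic": float("nan"), "p": 1.0,
                "n_set": int(in_set.sum()), "n_rest": 0}
    alternative = {"up": "greater", "down": "less", "either": "two-sided"}[direction]
    res = stats.mannwhitneyu(x, rest, alternative=alternative,
                             method="asymptotic")
    auc = float(res.statistic) / (len(x) * len(rest))
    return {"statistic": auc, "p": float(res.pvalue),
            "n_set": len(x), "n_rest": len(rest)}


def enrichment_table(expr: ExpressionMatrix, registry: ConditionRegistry,
                     panel: GenePanel, day: int = 7,
                     fdr_threshold: float = 0.05,
                     direction: str = "up",
                     baseline: int = BASELINE_CONDITION) -> pd.DataFrame:
    """Condition ranking by wanted/unwanted gene-set enrichment FDR.

    Every factorial condition (the baseline itself excluded) is
    contrasted against the baseline; FDRs are BH across conditions
    within each set.  Sorted by wanted FDR (ascending, ties by condition
    id); ``enriched_wanted_only`` flags conditions with wanted FDR below
    the threshold and unwanted FDR at or above it.
    """
    day_conds = set(expr.samples.loc[expr.samples["day"] == day,
                                     "condition_id"])
    if baseline not in day_conds:
        raise ValueError(
            f"baseline condition {baseline} absent from day {day} samples")
    conds = [c for c in registry.factorial_ids
             if c != baseline and c in day_conds]
    fit = fit_genewise_models(expr, day)
    rows = []
    for cid in conds:
        spec = ContrastSpec(f"c{cid}_vs_{baseline}", cid, baseline)
        res = contrast_de(expr, spec, day, fit=fit)
        row = {"condition_id": cid}
        for name in ("wanted", "unwanted"):
            gs = gene_set_test(res["t_mod"], panel.marker_set(name), direction)
            row[f"{name}_p"] = gs["p"]
            row[f"{name}_auc"] = gs["statistic"]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("condition_id")
    for name in ("wanted", "unwanted"):
        table[f"{name}_fdr"] = bh_adjust(table[f"{name}_p"].to_numpy())
    table["enriched_wanted_only"] = (
        (table["wanted_fdr"] < fdr_threshold)
        & (table["unwanted_fdr"] >= fdr_threshold))
    table = table.sort_index().sort_values("wanted_fdr", kind="mergesort")
    return table


@dataclasses.dataclass
class PCAResult:
    """Sample scores, gene loadings and variance-explained fractions."""

    scores: pd.DataFrame              # samples x components
    loadings: pd.DataFrame            # genes x components
    explained_variance_ratio: np.ndarray


def pca(expr: ExpressionMatrix | pd.DataFrame, center: bool = True,
        scale: bool = False, n_components: int | None = None) -> PCAResult:
    """Gene-centered SVD principal component analysis.

    Samples are observations, genes variables.  The sign of each
    component is fixed by making the gene with the largest absolute
    loading positive.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    M = values.to_numpy(dtype=float).T          # samples x genes
    if center:
        M = M - M.mean(axis=0, keepdims=True)
    if scale:
        sd = M.std(axis=0, ddof=1, keepdims=True)
        if (sd == 0).any():
            raise ValueError("cannot scale: some genes are constant")
        M = M / sd
    if not np.any(M):
        raise ValueError("matrix is constant; PCA is degenerate")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    k = len(s) if n_components is None else min(n_components, len(s))
    for j in range(k):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    comp = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U[:, :k] * s[:k], index=values.columns,
                          columns=comp)
    loadings = pd.DataFrame(Vt[:k].T, index=values.index, columns=comp)
    evr = s ** 2 / float((s ** 2).sum())
    return PCAResult(scores=scores, loadings=loadings,
                     explained_variance_ratio=evr[:k])


def heatmap_order(panel: GenePanel, score_table: pd.DataFrame,
                  ) -> tuple[list[str], list[int]]:
    """Deterministic heatmap layout: marker rows grouped by set then
    symbol, condition columns by wanted-score rank."""
    rows = sorted(panel.wanted) + sorted(panel.unwanted)
    cols = list(score_table.sort_values("rank").index)
    return rows, cols


class ScreenPCA(BaseEstimator):
    """Estimator wrapper of the gene-centered SVD PCA."""

    def __init__(self, center: bool = True, scale: bool = False,
                 n_components: int | None = None):
        self.center = center
        self.scale = scale
        self.n_components = n_components

    def fit(self, X: ExpressionMatrix, y=None):
        res = pca(X, self.center, self.scale, self.n_components)
        self.scores_ = res.scores
        self.loadings_ = res.loadings
        self.explained_variance_ratio_ = res.explained_variance_ratio
        return self

    def fit_transform(self, X: ExpressionMatrix, y=None) -> pd.DataFrame:
        self.fit(X)
        return self.scores_
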