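"""Factorial effect and interaction inference on marker-score responses.

For a complete two-level factorial with replicates, the effect of a term
is the mean response at its high level minus the mean at its low level.
Two equivalent computations are carried side by side as an internal
consistency check: twice the least-squares coefficient of the +-1 coded
column, and the classical Yates contrast divided by 2^(k-1) times the
replicate count; they must agree to 1e-10.

Standard errors come from the replicate-based residual mean square of
the blocked linear model (donor blocks removed; interactions above the
modeled order pooled into error), t statistics are effect / SE, and the
normal-plot coordinates pair the ordered standardized effects with
normal quantiles at (i - 0.375) / (n + 0.25).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix
from .design import (
    FACTORS, ConditionRegistry, GenePanel, ModelMatrix, encode_model_matrix,
)

__all__ = [
    "EffectTable", "estimate_effects", "test_effects", "boxcox_transform",
    "boxcox_apply", "interaction_summary", "marker_responses",
    "FactorialEffects",
]


@dataclasses.dataclass
class EffectTable:
    """Factorial effect estimates with (optional) inference columns.

    ``table`` is indexed by term with columns ``order``, ``effect`` and,
    after :func:`test_effects`, ``se``, ``t``, ``p``, ``significant``.
    """

    table: pd.DataFrame
    residual_ms: float
    residual_df: int
    n_obs: int
    response: str = ""
    transform: str | None = None
    alpha: float | None = None
    normal_plot: pd.DataFrame | None = None


def estimate_effects(y: pd.Series | np.ndarray, mm: ModelMatrix,
                     response: str = "") -> EffectTable:
    """Least-squares factorial effects of a complete two-level design.

    ``y`` holds one response per design row (replicates included);
    ``mm`` is the coded model matrix.  The design must be complete and
    balanced: every +-1 effect column must sum to zero and any two
    effect columns must be orthogonal.
    """
    y = np.asarray(y, dtype=float)
    X = mm.X.to_numpy(dtype=float)
    if len(y) != len(X):
        raise ValueError(f"{len(y)} responses for {len(X)} design rows")
    eff_cols = mm.X[mm.terms].to_numpy(dtype=float)
    gram = eff_cols.T @ eff_cols
    if not np.allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-9) or \
            not np.allclose(eff_cols.sum(axis=0), 0, atol=1e-9):
        raise ValueError(
            "effect columns are not balanced/orthogonal: the design has "
            "incomplete cells")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    coef = pd.Series(coef, index=mm.X.columns)
    effects_ls = 2.0 * coef[mm.terms]
    # Yates contrast: sum of +-1-weighted responses over half the runs
    effects_yates = pd.Series(eff_cols.T @ y / (len(y) / 2.0), index=mm.terms)
    if (effects_ls - effects_yates).abs().max() > 1e-10 * max(
            1.0, np.abs(y).max()):
        raise AssertionError(
            "regression and Yates-contrast effect estimates disagree")
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    df = len(y) - X.shape[1]
    ms = float(resid @ resid / df) if df > 0 else float("nan")
    table = pd.DataFrame({
        "order": pd.Series(mm.orders),
        "effect": effects_ls,
    }).loc[mm.terms]
    return EffectTable(table=table, residual_ms=ms, residual_df=df,
                       n_obs=len(y), response=response)


def test_effects(et: EffectTable, alpha: float = 0.05) -> EffectTable:
    """Standardized effects, p-values, flags and normal-plot coordinates."""
    if et.residual_df < 1 or not np.isfinite(et.residual_ms):
        raise ValueError(
            "zero residual degrees of freedom: pool higher-order terms "
            "into error (lower max_order) or add replicates")
    table = et.table.copy()
    se = 2.0 * np.sqrt(et.residual_ms / et.n_obs)
    table["se"] = se
    table["t"] = table["effect"] / se
    table["p"] = 2.0 * stats.t.sf(np.abs(table["t"]), et.residual_df)
    table["significant"] = table["p"] < alpha
    n = len(table)
    ordered = table["t"].sort_values(kind="mergesort")
    q = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    normal_plot = pd.DataFrame({
        "term": ordered.index, "t": ordered.to_numpy(),
        "normal_quantile": q,
    }).set_index("term")
    return EffectTable(table=table, residual_ms=et.residual_ms,
                       residual_df=et.residual_df, n_obs=et.n_obs,
                       response=et.response, transform=et.transform,
                       alpha=alpha, normal_plot=normal_plot)


def boxcox_transform(y, shift: float = 0.0) -> dict:
    """Box-Cox power transform with a profile-likelihood lambda.

    lambda is chosen on the grid [-2, 2] in steps of 0.01; the responses
    must be positive after the configured shift.
    """
    y = np.asarray(y, dtype=float) + shift
    if (y <= 0).any():
        raise ValueError(
            "responses must be positive after the shift; supply a larger "
            "shift")
    grid = np.round(np.arange(-200, 201)) / 100.0
    llf = np.array([stats.boxcox_llf(lam, y) for lam in grid])
    lam = float(grid[int(np.argmax(llf))])
    return {"lambda": lam, "shift": shift,
            "transformed": boxcox_apply(y, lam)}


def boxcox_apply(y, lam: float) -> np.ndarray:
    """The Box-Cox power transform at a given lambda:
    (y^lambda - 1) / lambda, with the log limit at lambda = 0."""
    y = np.asarray(y, dtype=float)
    if lam == 0.0:
        return np.log(y)
    return (y ** lam - 1.0) / lam


def marker_responses(expr: ExpressionMatrix, panel: GenePanel,
                     which: str = "wanted", day: int = 7,
                     registry: ConditionRegistry | None = None,
                     arm: str = "factorial",
                     studentize_genes: bool = True) -> pd.DataFrame:
    """Per-(condition, donor) marker-set mean response for effect fitting.

    Each gene is optionally standardized across the selected samples so
    the set mean weights genes equally; the response of a sample is the
    mean over the marker set.
    """
    samples = expr.samples
    mask = samples["day"] == day
    if registry is not None:
        ok = set(registry.arm_ids(arm))
        mask &= samples["condition_id"].isin(ok)
    sub = expr.values.loc[:, mask[mask].index]
    members = [g for g in panel.marker_set(which) if g in sub.index]
    if not members:
        raise ValueError(f"marker set {which!r} absent from the matrix")
    vals = sub.loc[members]
    if studentize_genes:
        sd = vals.std(axis=1, ddof=1).replace(0.0, 1.0)
        vals = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    resp = vals.mean(axis=0)
    out = samples.loc[resp.index, ["condition_id", "donor"]].copy()
    out["response"] = resp
    return out


def interaction_summary(responses: pd.DataFrame, registry: ConditionRegistry,
                        pair: tuple[str, str]) -> dict:
    """2x2 presence/absence cell means of a factor pair, averaged over the
    other factors and donors, plus the synergy index
    (both - a_only - b_only + neither)."""
    a, b = pair
    for f in pair:
        if f not in FACTORS:
            raise KeyError(f"unknown factor {f!r}")
    resp = responses.copy()
    conds = resp["condition_id"].astype(int)
    resp["a_on"] = [registry.lookup(c).active(a) for c in conds]
    resp["b_on"] = [registry.lookup(c).active(b) for c in conds]
    cells = resp.groupby(["a_on", "b_on"])["response"].mean()
    grid = pd.DataFrame(
        [[cells.get((False, False), np.nan), cells.get((False, True), np.nan)],
         [cells.get((True, False), np.nan), cells.get((True, True), np.nan)]],
        index=pd.Index([False, True], name=a),
        columns=pd.Index([False, True], name=b))
    synergy = float(grid.loc[True, True] - grid.loc[True, False]
                    - grid.loc[False, True] + grid.loc[False, False])
    return {"cells": grid, "synergy": synergy}


class FactorialEffects(BaseEstimator):
    """Estimator for the factorial screen analysis of one marker response.

    ``fit`` takes the normalized expression, builds the marker-set
    response, codes the complete factorial model with donor blocks and
    estimates/tests all effects up to ``max_order``.  Fitted attributes:
    ``responses_``, ``effect_table_`` (:class:`EffectTable` with
    inference columns) and ``normal_plot_``.
    """

    def __init__(self, response: str = "wanted", day: int = 7,
                 max_order: int = 3, alpha: float = 0.05):
        self.response = response
        self.day = day
        self.max_order = max_order
        self.alpha = alpha

    def fit(self, X: ExpressionMatrix, panel: GenePanel,
            registry: ConditionRegistry):
        resp = marker_responses(X, panel, self.response, self.day,
                                registry=registry)
        design = X.samples.loc[resp.index]
        mm = encode_model_matrix(design, registry, self.max_order)
        et = estimate_effects(resp["response"], mm, response=self.response)
        self.responses_ = resp
        self.effect_table_ = test_effects(et, self.alpha)
        self.normal_plot_ = self.effect_table_.normal_plot
        return self
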