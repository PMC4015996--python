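"""Count normalization: lane scaling, reference-gene selection, glog.

The chain turns raw digital counts into log2-scale expression:

1. **Lane scaling** equalizes the geometric mean of the spike-in
   positive controls across samples (the per-sample factor is the grand
   geometric mean of those means divided by the sample's mean).
2. **Reference-gene selection** ranks housekeeping candidates with a
   NormFinder-type variance decomposition: per candidate gene a
   within-group variance (residuals of the additive gene + sample model,
   with the multi-candidate bias correction) and a between-group bias
   (the candidate's double-centered group mean, shrunk toward zero by
   its sampling variance) combine into the stability value

       rho = mean over groups of ( |d_hat_g| + sigma_hat_g ),

   lower is more stable.
3. **Reference normalization** rescales each sample so the geometric
   mean of the selected references equals its across-sample grand
   geometric mean.
4. **glog** applies the variance-stabilizing generalized logarithm
   ``h(x) = log2((x + sqrt(x^2 + c^2)) / 2)`` -- log2-like for x >> c,
   bounded variance near zero -- with the offset c set from the
   negative-control background by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CountMatrix, ExpressionMatrix

__all__ = [
    "NormalizationError", "lane_scale_factors", "normfinder_stability",
    "select_references", "reference_normalize", "glog_transform",
    "normalize_screen", "NanoStringNormalizer",
]


class NormalizationError(ValueError):
    """Normalization cannot proceed on these inputs."""


def _geomean(cols: pd.DataFrame, pseudo_count: float | None,
             what: str, log: list | None = None) -> pd.Series:
    """Per-column geometric mean; zeros raise unless a pseudo-count is
    configured (applied, and logged, only when zeros occur)."""
    vals = cols.to_numpy(dtype=float)
    if (vals == 0).any():
        if pseudo_count is None:
            s = cols.columns[np.argwhere(vals == 0)[0, 1]]
            raise NormalizationError(
                f"zero {what} count in sample {s!r} breaks the geometric "
                f"mean; configure a pseudo-count to proceed")
        vals = vals + pseudo_count
        if log is not None:
            log.append({"event": "pseudo_count", "where": what,
                        "pseudo_count": pseudo_count})
    return pd.Series(np.exp(np.log(vals).mean(axis=0)), index=cols.columns)


def lane_scale_factors(cm: CountMatrix,
                       pseudo_count: float | None = None,
                       log: list | None = None) -> pd.Series:
    """Per-sample lane scale factors from the positive-control series.

    ``factor_s = G / g_s`` with ``g_s`` the positive-control geometric
    mean of sample ``s`` and ``G`` the geometric mean of the ``g_s``
    across samples; multiplying sample ``s`` by its factor equalizes the
    positive-control geometric means.
    """
    pos = cm.class_rows("positive_ctrl")
    if len(pos) < 1:
        raise NormalizationError("no positive-control probes present")
    g = _geomean(pos, pseudo_count, "positive-control", log)
    grand = float(np.exp(np.log(g).mean()))
    return grand / g


def normfinder_stability(log_expr: pd.DataFrame,
                         groups: pd.Series) -> pd.DataFrame:
    """NormFinder-type stability of candidate reference genes.

    Parameters
    ----------
    log_expr
        Candidates x samples matrix on a log scale.
    groups
        Sample -> group label (the grouping whose systematic differences
        a reference gene must not track; day by default in the pipeline).

    Returns
    -------
    DataFrame indexed by candidate with per-group ``sigma[g]`` /
    ``d[g]`` columns, combined stability ``rho`` (lower = more stable)
    and ``rank`` (ties broken lexicographically by symbol).
    """
    k = len(log_expr)
    if k < 3:
        raise NormalizationError(
            f"need at least 3 candidate genes for the stability model, got {k}")
    groups = groups.loc[log_expr.columns]
    lvls = list(pd.unique(groups))
    for g in lvls:
        if (groups == g).sum() < 2:
            raise NormalizationError(
                f"group {g!r} has fewer than 2 samples")

    # per-group intra variance with the multi-candidate bias correction
    sigma2 = pd.DataFrame(index=log_expr.index, columns=lvls, dtype=float)
    gmeans = pd.DataFrame(index=log_expr.index, columns=lvls, dtype=float)
    for g in lvls:
        Y = log_expr.loc[:, groups[groups == g].index].to_numpy(dtype=float)
        n = Y.shape[1]
        resid = Y - Y.mean(1, keepdims=True) - Y.mean(0, keepdims=True) \
            + Y.mean()
        ms = (resid ** 2).sum(1) / (n - 1)
        est = (ms - ms.mean() / (k - 1)) * k / (k - 2)
        sigma2[g] = np.clip(est, 0.0, None)
        gmeans[g] = Y.mean(1)

    # between-group bias: double-centered group means, shrunk toward 0
    d = gmeans.sub(gmeans.mean(axis=1), axis=0)
    d = d.sub(d.mean(axis=0), axis=1)
    n_per = {g: int((groups == g).sum()) for g in lvls}
    d_shrunk = pd.DataFrame(index=log_expr.index, columns=lvls, dtype=float)
    for g in lvls:
        samp_var = sigma2[g] / n_per[g]
        if len(lvls) == 1:
            d_shrunk[g] = 0.0
            continue
        tau2 = max(0.0, float(d[g].var(ddof=1)) - float(samp_var.mean()))
        with np.errstate(invalid="ignore"):
            w = tau2 / (tau2 + samp_var)
        d_shrunk[g] = (d[g] * w.fillna(0.0)).fillna(0.0)

    rho = pd.Series(0.0, index=log_expr.index)
    for g in lvls:
        rho += d_shrunk[g].abs() + np.sqrt(sigma2[g])
    rho /= len(lvls)

    table = pd.DataFrame({"rho": rho})
    for g in lvls:
        table[f"sigma[{g}]"] = np.sqrt(sigma2[g])
        table[f"d[{g}]"] = d_shrunk[g]
    # stable sort of a lexicographically pre-sorted frame = documented tie-break
    order = table.loc[sorted(table.index)].sort_values("rho", kind="mergesort")
    table["rank"] = pd.Series(range(1, k + 1), index=order.index)
    return table.sort_values("rank")


def select_references(stability: pd.DataFrame, n_refs: int = 5) -> list[str]:
    """The ``n_refs`` most stable candidates (lowest rho; ties broken
    lexicographically by symbol)."""
    if n_refs > len(stability):
        raise ValueError(
            f"n_refs={n_refs} exceeds the {len(stability)} candidates")
    return list(stability.sort_values("rank").index[:n_refs])


def reference_normalize(cm: CountMatrix, refs: list[str],
                        pseudo_count: float | None = None,
                        log: list | None = None) -> CountMatrix:
    """Rescale each sample so the geometric mean of the reference genes
    equals the across-sample grand geometric mean of the references."""
    missing = [r for r in refs if r not in cm.values.index]
    if missing:
        raise NormalizationError(f"reference genes absent: {missing}")
    g = _geomean(cm.values.loc[refs], pseudo_count, "reference", log)
    grand = float(np.exp(np.log(g).mean()))
    values = cm.values * (grand / g)
    return CountMatrix(values, cm.genes, cm.samples, require_int=False)


def glog_offset(cm: CountMatrix, offset_policy: str = "negctrl",
                c: float | None = None, quantile: float = 0.05) -> float:
    """Resolve the glog offset ``c`` under the configured policy."""
    if offset_policy == "fixed":
        if c is None or c <= 0:
            raise ValueError("fixed offset policy requires c > 0")
        return float(c)
    if offset_policy == "negctrl":
        neg = cm.class_rows("negative_ctrl")
        if len(neg) == 0:
            raise NormalizationError(
                "negctrl offset policy needs negative-control probes")
        return float(neg.to_numpy().mean())
    if offset_policy == "quantile":
        endo = cm.values[cm.genes["cls"].isin(
            ("endogenous", "housekeeping_candidate"))]
        return float(np.quantile(endo.to_numpy(), quantile))
    raise ValueError(f"unknown offset policy {offset_policy!r}")


def glog(x, c: float):
    """Generalized log: ``log2((x + sqrt(x^2 + c^2)) / 2)``."""
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x * x + c * c)) / 2.0)


def glog_transform(cm: CountMatrix, offset_policy: str = "negctrl",
                   c: float | None = None, quantile: float = 0.05,
                   ) -> ExpressionMatrix:
    """Apply the generalized log and drop the control probes.

    Also flags genes whose median count is below the negative-control
    background (mean + 2 sd); the flag is recorded, nothing is filtered.
    """
    c_val = glog_offset(cm, offset_policy, c, quantile)
    keep = cm.genes["cls"].isin(("endogenous", "housekeeping_candidate"))
    values = pd.DataFrame(glog(cm.values[keep].to_numpy(), c_val),
                          index=cm.values.index[keep], columns=cm.values.columns)
    genes = cm.genes[keep].copy()
    neg = cm.class_rows("negative_ctrl")
    if len(neg):
        thr = float(neg.to_numpy().mean() + 2 * neg.to_numpy().std(ddof=1))
        genes["below_background"] = (
            cm.values[keep].median(axis=1) < thr)
    meta = {"glog_c": c_val, "offset_policy": offset_policy}
    return ExpressionMatrix(values, genes, cm.samples.copy(), meta)


def normalize_screen(cm: CountMatrix, n_refs: int = 5,
                     group_by: str = "day", offset_policy: str = "negctrl",
                     fixed_c: float | None = None,
                     pseudo_count: float | None = 0.5,
                     ) -> tuple[ExpressionMatrix, dict]:
    """Full chain: lane scaling -> stability ranking -> reference
    normalization -> glog.  Returns the expression matrix and a
    provenance record (factors, stability table, references, offset,
    pseudo-count events)."""
    events: list = []
    factors = lane_scale_factors(cm, pseudo_count, events)
    scaled = CountMatrix(cm.values * factors, cm.genes, cm.samples,
                         require_int=False)
    candidates = scaled.values[scaled.genes["cls"] == "housekeeping_candidate"]
    if len(candidates) < max(3, n_refs):
        raise NormalizationError(
            f"{len(candidates)} housekeeping candidates present; "
            f"need at least {max(3, n_refs)}")
    log_cand = np.log2(candidates.where(candidates > 0, pseudo_count or np.nan))
    if log_cand.isna().any().any():
        raise NormalizationError(
            "zero candidate counts; configure a pseudo-count")
    stability = normfinder_stability(log_cand, scaled.samples[group_by])
    refs = select_references(stability, n_refs)
    refnormed = reference_normalize(scaled, refs, pseudo_count, events)
    expr = glog_transform(refnormed, offset_policy, fixed_c)
    expr.meta.update({
        "lane_factors": factors.to_dict(),
        "references": refs,
        "n_refs": n_refs,
        "group_by": group_by,
        "events": events,
    })
    provenance = {
        "references": refs,
        "glog_c": expr.meta["glog_c"],
        "offset_policy": offset_policy,
        "pseudo_count": pseudo_count,
        "stability": stability["rho"].to_dict(),
        "events": events,
    }
    return expr, provenance


class NanoStringNormalizer(BaseEstimator, TransformerMixin):
    """Estimator wrapper of the normalization chain.

    ``fit`` learns the lane factors, reference-gene ranking and glog
    offset from a :class:`CountMatrix`; ``transform`` applies the chain.
    Fitted attributes: ``lane_factors_``, ``stability_``,
    ``references_``, ``glog_c_``.
    """

    def __init__(self, n_refs: int = 5, group_by: str = "day",
                 offset_policy: str = "negctrl", fixed_c: float | None = None,
                 pseudo_count: float | None = 0.5):
        self.n_refs = n_refs
        self.group_by = group_by
        self.offset_policy = offset_policy
        self.fixed_c = fixed_c
        self.pseudo_count = pseudo_count

    def fit(self, X: CountMatrix, y=None):
        if not isinstance(X, CountMatrix):
            raise TypeError("NanoStringNormalizer expects a CountMatrix")
        expr, prov = normalize_screen(
            X, self.n_refs, self.group_by, self.offset_policy,
            self.fixed_c, self.pseudo_count)
        self.lane_factors_ = pd.Series(expr.meta["lane_factors"])
        self.references_ = prov["references"]
        self.stability_ = prov["stability"]
        self.glog_c_ = prov["glog_c"]
        self.provenance_ = prov
        return self

    def transform(self, X: CountMatrix) -> ExpressionMatrix:
        if not hasattr(self, "references_"):
            raise RuntimeError("NanoStringNormalizer is not fitted")
        events: list = []
        factors = lane_scale_factors(X, self.pseudo_count, events)
        scaled = CountMatrix(X.values * factors, X.genes, X.samples,
                             require_int=False)
        refnormed = reference_normalize(scaled, self.references_,
                                        self.pseudo_count, events)
        expr = glog_transform(refnormed, "fixed", self.glog_c_)
        expr.meta.update({"lane_factors": factors.to_dict(),
                          "references": self.references_, "events": events})
        return expr

    def fit_transform(self, X: CountMatrix, y=None, **kwargs) -> ExpressionMatrix:
        self.fit(X)
        expr, _ = normalize_screen(
            X, self.n_refs, self.group_by, self.offset_policy,
            self.fixed_c, self.pseudo_count)
        return expr
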