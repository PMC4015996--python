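"""Gene-wise contrasts with empirical-Bayes variance moderation.

Each contrast compares two conditions at one day with donor as a fixed
blocking covariate (donors are paired across conditions), giving per
gene a log2 fold change, a residual variance and its degrees of
freedom.  Residual variances are then shrunk across genes toward a
common prior: assuming s^2 ~ s0^2 * F(df, d0), the prior degrees of
freedom d0 and prior variance s0^2 are estimated by the method of
moments on log s^2 (digamma/trigamma inversion) and the posterior
variance is

    s~^2 = (d0 * s0^2 + df * s^2) / (d0 + df),

used in a moderated t with df + d0 degrees of freedom.  Significance
calls combine a fold-change cut-off (twofold by default, |log2FC| >= 1)
with a Benjamini-Hochberg FDR threshold (5% by default), applied per
contrast across genes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix
from .design import FACTORS, ConditionRegistry, DesignError

__all__ = [
    "ContrastSpec", "ModerationParams", "GenewiseFit",
    "fit_genewise_models", "fit_genewise_contrast",
    "moderate_variance", "squeeze_variances", "bh_adjust", "call_de",
    "contrast_de", "uniform_factor_genes", "contrast_overlap",
    "ModeratedContrast", "BASELINE_CONDITION",
]

#: The no-factor baseline medium every Fig-5-style comparison is made against.
BASELINE_CONDITION = 32


@dataclasses.dataclass(frozen=True)
class ContrastSpec:
    """A vs B condition contrast (log2FC = mean A - mean B)."""

    name: str
    condition_a: int
    condition_b: int
    interpretation: str = ""

    def __post_init__(self):
        if self.condition_a == self.condition_b:
            raise ValueError("contrast conditions must differ")


@dataclasses.dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes prior: degrees of freedom d0 (inf allowed) and
    prior variance s0^2."""

    d0: float
    s02: float


@dataclasses.dataclass
class GenewiseFit:
    """Per-gene linear-model fit of one day of the screen.

    The model is expression ~ condition + donor over every selected
    sample, fitted to all genes at once; ``means`` holds the
    donor-adjusted condition means, ``s2`` the pooled residual variance
    per gene on ``df`` degrees of freedom.
    """

    means: pd.DataFrame            # genes x condition ids
    s2: pd.Series
    df: int
    n_rep: pd.Series               # replicates per condition

    def fc(self, condition_a: int, condition_b: int) -> pd.Series:
        return self.means[condition_a] - self.means[condition_b]

    def fc_var_factor(self, condition_a: int, condition_b: int) -> float:
        return 1.0 / self.n_rep[condition_a] + 1.0 / self.n_rep[condition_b]


def fit_genewise_models(expr: ExpressionMatrix, day: int = 7,
                        conditions=None) -> GenewiseFit:
    """Fit the donor-blocked gene-wise linear model of one day.

    One model over all selected conditions pools the residual variance
    across the whole day (the usual linear-model practice for
    multi-condition screens), so every contrast shares the same
    per-gene ``s2`` and residual ``df``.
    """
    samples = expr.samples
    mask = samples["day"] == day
    if conditions is not None:
        mask &= samples["condition_id"].isin(conditions)
    sel = samples[mask]
    conds = sorted(sel["condition_id"].unique())
    reps = sel.groupby("condition_id").size()
    if (reps < 2).any():
        few = reps[reps < 2].index.tolist()
        raise DesignError(
            f"conditions with fewer than 2 replicates at day {day}: {few}")
    cond_idx = {c: i for i, c in enumerate(conds)}
    donors = sorted(sel["donor"].unique())
    n = len(sel)
    p = len(conds) + max(0, len(donors) - 1)
    X = np.zeros((n, p))
    for row, (sid, meta) in enumerate(sel.iterrows()):
        X[row, cond_idx[meta["condition_id"]]] = 1.0
        d = donors.index(meta["donor"])
        if d > 0:
            X[row, len(conds) + d - 1] = 1.0
    Y = expr.values[sel.index].to_numpy().T       # samples x genes
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    df = n - rank
    if df < 1:
        raise DesignError("no residual degrees of freedom in the gene-wise model")
    s2 = (resid ** 2).sum(axis=0) / df
    # donor-reference offset cancels in any condition contrast
    means = pd.DataFrame(coef[:len(conds)].T, index=expr.values.index,
                         columns=conds)
    return GenewiseFit(means=means, s2=pd.Series(s2, index=expr.values.index),
                       df=int(df), n_rep=reps)


def fit_genewise_contrast(expr: ExpressionMatrix, contrast: ContrastSpec,
                          day: int = 7) -> pd.DataFrame:
    """Donor-blocked per-gene fit restricted to one contrast's samples.

    Returns a DataFrame indexed by gene with ``log2fc``, ``s2``
    (residual variance of the blocked two-condition model), ``df`` and
    ``n_rep``.  :func:`contrast_de` pools variance across the whole day
    instead; this restricted fit is the building block the pooled model
    generalizes.
    """
    samples = expr.samples
    sel_a = (samples["day"] == day) & (samples["condition_id"] == contrast.condition_a)
    sel_b = (samples["day"] == day) & (samples["condition_id"] == contrast.condition_b)
    a_cols = samples[sel_a].sort_values("donor")
    b_cols = samples[sel_b].sort_values("donor")
    if list(a_cols["donor"]) != list(b_cols["donor"]):
        raise DesignError(
            f"contrast {contrast.name!r}: donors differ between conditions")
    r = len(a_cols)
    if r < 2:
        raise DesignError(
            f"contrast {contrast.name!r}: need >= 2 replicates, got {r}")
    ya = expr.values[a_cols.index].to_numpy()
    yb = expr.values[b_cols.index].to_numpy()
    d = ya - yb                       # paired differences, donor block removed
    log2fc = d.mean(axis=1)
    # residual MS of the 2 x r blocked fit: Var(d)/2 on r-1 df
    s2 = d.var(axis=1, ddof=1) / 2.0
    return pd.DataFrame({
        "log2fc": log2fc, "s2": s2,
        "df": r - 1, "n_rep": r,
    }, index=expr.values.index)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return float("inf")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderate_variance(s2, df: int) -> tuple[ModerationParams, np.ndarray]:
    """Estimate the variance prior and squeeze the per-gene variances.

    Hyperparameters are fitted by the method of moments on log s^2: with
    s^2 ~ s0^2 * F(df, d0),

        Var(log s^2)  = trigamma(df/2) + trigamma(d0/2)
        E(log s^2)    = log s0^2 + digamma(df/2) - log(df/2)
                        - digamma(d0/2) + log(d0/2).

    If the observed spread of log s^2 does not exceed trigamma(df/2),
    the prior is degenerate (d0 = inf) and every posterior variance
    equals s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if len(pos) < 10:
        raise ValueError(
            f"need >= 10 positive variances to fit the prior, got {len(pos)}")
    e = np.log(pos)
    target = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    emean_df = special.digamma(df / 2.0) - np.log(df / 2.0)
    if target <= 1e-12:
        params = ModerationParams(
            d0=float("inf"), s02=float(np.exp(e.mean() - emean_df)))
    else:
        x = _trigamma_inverse(float(target))
        d0 = 2.0 * x
        s02 = float(np.exp(e.mean() - emean_df
                           + special.digamma(x) - np.log(x)))
        params = ModerationParams(d0=d0, s02=s02)
    return params, squeeze_variances(s2, df, params)


def squeeze_variances(s2, df: int, params: ModerationParams) -> np.ndarray:
    """Posterior variances (d0*s0^2 + df*s^2) / (d0 + df)."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(params.d0):
        return np.full_like(s2, params.s02)
    return (params.d0 * params.s02 + df * s2) / (params.d0 + df)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in original order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_de(results: pd.DataFrame, fc_threshold: float = 1.0,
            q_threshold: float = 0.05) -> pd.DataFrame:
    """Apply the fold-change + FDR significance rule.

    ``significant`` iff |log2fc| >= fc_threshold and q < q_threshold;
    ``direction`` is ``up`` / ``down`` by the sign of the fold change.
    """
    if fc_threshold <= 0 or q_threshold <= 0:
        raise ValueError("thresholds must be positive")
    out = results.copy()
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    out["significant"] = (out["log2fc"].abs() >= fc_threshold) \
        & (out["q"] < q_threshold)
    return out


def contrast_de(expr: ExpressionMatrix, contrast: ContrastSpec, day: int = 7,
                fc_threshold: float = 1.0, q_threshold: float = 0.05,
                moderate: bool = True,
                fit: GenewiseFit | None = None) -> pd.DataFrame:
    """Full per-gene contrast: fit, moderation, p, BH q, significance.

    ``fit`` may carry a precomputed day-level gene-wise model (shared by
    condition batteries); otherwise the day's model is fitted here.
    """
    if fit is None:
        fit = fit_genewise_models(expr, day)
    for c in (contrast.condition_a, contrast.condition_b):
        if c not in fit.means.columns:
            raise DesignError(f"condition {c} absent from the fitted model")
    log2fc = fit.fc(contrast.condition_a, contrast.condition_b)
    vf = fit.fc_var_factor(contrast.condition_a, contrast.condition_b)
    df = fit.df
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = log2fc / np.sqrt(vf * fit.s2)
    out = pd.DataFrame({"log2fc": log2fc, "s2": fit.s2, "df": df,
                        "t_ord": t_ord})
    if moderate:
        params, s2_tilde = moderate_variance(fit.s2.to_numpy(), df)
        out["s2_tilde"] = s2_tilde
        out["t_mod"] = log2fc / np.sqrt(vf * s2_tilde)
        df_total = df + params.d0
        if np.isinf(df_total):
            out["p"] = 2.0 * stats.norm.sf(np.abs(out["t_mod"]))
        else:
            out["p"] = 2.0 * stats.t.sf(np.abs(out["t_mod"]), df_total)
        out.attrs["moderation"] = params
    else:
        out["t_mod"] = out["t_ord"]
        out["p"] = 2.0 * stats.t.sf(np.abs(out["t_ord"]), df)
    out["p"] = out["p"].fillna(1.0)
    out["q"] = bh_adjust(out["p"].to_numpy())
    res = call_de(out, fc_threshold, q_threshold)
    res.attrs.update(out.attrs)
    return res


def uniform_factor_genes(expr: ExpressionMatrix, registry: ConditionRegistry,
                         factor: str, day: int = 7,
                         fc_threshold: float = 1.0,
                         q_threshold: float = 0.05,
                         baseline: int = BASELINE_CONDITION,
                         fit: GenewiseFit | None = None) -> dict:
    """Genes consistently regulated by one factor across the whole arm.

    A gene qualifies iff it is called significant versus the baseline
    condition in *all* factorial conditions containing the factor, with
    the same direction everywhere.  Returns ``{"up": [...], "down":
    [...]}``.
    """
    if factor not in FACTORS:
        raise KeyError(f"unknown factor {factor!r}")
    conds = [c for c in registry.factorial_ids
             if registry.lookup(c).active(factor) and c != baseline]
    if fit is None:
        fit = fit_genewise_models(expr, day)
    up = None
    down = None
    for cid in conds:
        spec = ContrastSpec(f"c{cid}_vs_{baseline}", cid, baseline)
        res = contrast_de(expr, spec, day, fc_threshold, q_threshold, fit=fit)
        sig_up = set(res.index[res["significant"] & (res["direction"] == "up")])
        sig_dn = set(res.index[res["significant"] & (res["direction"] == "down")])
        up = sig_up if up is None else up & sig_up
        down = sig_dn if down is None else down & sig_dn
    return {"up": sorted(up or ()), "down": sorted(down or ()),
            "n_conditions": len(conds)}


def contrast_overlap(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Overlap of the significant gene sets of two contrasts, split by
    direction (same direction in both contrasts)."""
    if not a.index.equals(b.index):
        raise ValueError("contrasts are on different gene universes")
    sig_a = a[a["significant"]]
    sig_b = b[b["significant"]]
    inter = sig_a.index.intersection(sig_b.index)
    same_dir = [g for g in inter
                if a.loc[g, "direction"] == b.loc[g, "direction"]]
    up = [g for g in same_dir if a.loc[g, "direction"] == "up"]
    down = [g for g in same_dir if a.loc[g, "direction"] == "down"]
    return {
        "n_a": int(len(sig_a)), "n_b": int(len(sig_b)),
        "n_overlap": len(same_dir),
        "genes_a": sorted(sig_a.index), "genes_b": sorted(sig_b.index),
        "overlap_up": sorted(up), "overlap_down": sorted(down),
    }


class ModeratedContrast(BaseEstimator):
    """Estimator wrapper of one moderated condition contrast."""

    def __init__(self, condition_a: int = 12, condition_b: int = 16,
                 day: int = 7, fc_threshold: float = 1.0,
                 q_threshold: float = 0.05, moderate: bool = True):
        self.condition_a = condition_a
        self.condition_b = condition_b
        self.day = day
        self.fc_threshold = fc_threshold
        self.q_threshold = q_threshold
        self.moderate = moderate

    def fit(self, X: ExpressionMatrix, y=None):
        spec = ContrastSpec(
            f"c{self.condition_a}_vs_c{self.condition_b}",
            self.condition_a, self.condition_b)
        self.results_ = contrast_de(
            X, spec, self.day, self.fc_threshold, self.q_threshold,
            self.moderate)
        self.moderation_ = self.results_.attrs.get("moderation")
        return self
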