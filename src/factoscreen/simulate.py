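"""Negative-binomial count simulator with planted factorial ground truth.

No raw data accession exists for this kind of screen, so every
downstream stage is exercised on synthetic digital counts whose
generative truth is known.  Counts are negative binomial
(Poisson-gamma) with

    mean = lane_factor * 2^(baseline log2 + donor offset + sum of planted effects)

for endogenous genes; spike-in positive controls follow the panel's
nominal concentration series times the lane factor, and negative
controls have a small constant background mean.  A dispersion of 0
degenerates to deterministic ``round(mean)`` (the noise-free limit), so
every variance knob can be switched off independently.

Planted effects attach a log2 shift to a gene (or a whole marker set)
whenever a factor term -- a single factor, an ``A:B`` interaction, or
the seeding-density profile -- is active in a sample's condition and the
sample's day is in the effect's scope.  The ``paper_like`` preset plants
the qualitative structure this screen design is meant to detect:
positive TGFB/DEX/BMP main effects on the wanted markers with a strong
TGFB:DEX synergy and a BMP damping interaction, a negative FGF2 effect,
no IGF1 effect, factor-specific single-gene responses (COL10A1 up under
TGFB1, BGLAP down under DEX), and day-7 effects twice the day-1 effects.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix
from . import design as design_mod
from .design import (
    ConditionRegistry, GenePanel, UNTREATED_ID, DEFAULT_DENSITY,
    build_condition_registry, build_default_panel, make_design_table,
)

__all__ = [
    "PlantedEffect", "SimulationConfig", "SimTruth", "SimConfigError",
    "simulate_counts", "simulate_null_screen",
    "paper_like_config", "null_config", "PAPER_LIKE_EFFECTS",
]


class SimConfigError(ValueError):
    """Simulation configuration violates an invariant."""


@dataclasses.dataclass(frozen=True)
class PlantedEffect:
    """A known log2 expression shift used as ground truth.

    ``target`` is a gene symbol or a marker-set name (``wanted`` /
    ``unwanted``); ``term`` is a factor token (``TGFB``, ``DEX``, ...),
    a ``:``-joined interaction, or ``density``; the shift applies on the
    days in ``day_scope``.
    """

    target: str
    term: str
    log2_effect: float
    day_scope: tuple[int, ...] = (1, 7)


@dataclasses.dataclass
class SimulationConfig:
    """Generative parameters of a synthetic screen.

    Variance parameters are all on the log2 scale except ``dispersion``,
    the negative-binomial overdispersion (Var = mu + dispersion * mu^2).
    """

    panel: GenePanel
    registry: ConditionRegistry
    n_donors: int = 3
    days: tuple[int, ...] = (0, 1, 7)
    arms: tuple[str, ...] = ("factorial", "isoform", "density")
    baseline_mean: float = 200.0
    gene_sd: float = 1.5          # per-gene baseline spread (log2)
    dispersion: float = 0.05
    lane_sd: float = 0.15         # per-sample scale spread (log2)
    donor_sd: float = 0.2         # per-(gene, donor) biological spread (log2)
    effects: list[PlantedEffect] = dataclasses.field(default_factory=list)
    seed: int = 0
    neg_mean: float = 4.0
    pos_unit: float = 500.0       # counts per nominal spike-in unit
    ctrl_dispersion: float = 0.005   # technical-only NB dispersion of controls
    n_stable_refs: int = 5
    hk_variance_factor: float = 0.25
    ref_instability_sd: float = 0.7   # day wobble of non-stable candidates

    def __post_init__(self) -> None:
        for name in ("baseline_mean",):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        for name in ("gene_sd", "dispersion", "lane_sd", "donor_sd",
                     "neg_mean", "ref_instability_sd", "ctrl_dispersion"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be non-negative")


@dataclasses.dataclass
class SimTruth:
    """Ground truth of a simulated screen (reproducible from config+seed)."""

    expected_log2: pd.DataFrame      # genes x (condition, day) generative log2 mean
    effects: list[PlantedEffect]
    stable_references: list[str]
    lane_log2: pd.Series             # per-sample lane factor (log2)
    donor_log2: pd.DataFrame         # genes x donors biological offsets


def _density_profile(density: float) -> float:
    """Unimodal density response: 0 at the default density, negative on
    either side of it (log2 distance)."""
    return -abs(math.log2(density / DEFAULT_DENSITY))


def _effect_delta(config: SimulationConfig, genes: Sequence[str],
                  ) -> dict[tuple[int, int], np.ndarray]:
    """Planted log2 shift per (condition, day), vector over genes."""
    panel = config.panel
    idx = {g: i for i, g in enumerate(genes)}
    out: dict[tuple[int, int], np.ndarray] = {}
    cond_ids = [UNTREATED_ID] + list(config.registry.ids)
    for cid in cond_ids:
        cond = config.registry.lookup(cid)
        for day in config.days:
            delta = np.zeros(len(genes))
            if cid != UNTREATED_ID:
                for eff in config.effects:
                    if day not in eff.day_scope:
                        continue
                    if eff.term == "density":
                        scale = _density_profile(cond.density)
                        if scale == 0.0:
                            continue
                    elif cond.term_active(eff.term):
                        scale = 1.0
                    else:
                        continue
                    if eff.target in ("wanted", "unwanted"):
                        targets = panel.marker_set(eff.target)
                    else:
                        targets = [eff.target]
                    for g in targets:
                        if g in idx:
                            delta[idx[g]] += eff.log2_effect * scale
            out[(cid, day)] = delta
    return out


def simulate_counts(config: SimulationConfig,
                    ) -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Draw one synthetic screen.

    Returns the raw count matrix (all probe classes), the design table
    and the generative ground truth.  Deterministic for a given config
    and seed.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    genes = panel.assay_symbols
    hk = panel.housekeeping_candidates
    stable = hk[:config.n_stable_refs]
    unstable = hk[config.n_stable_refs:]

    design = make_design_table(config.registry, config.n_donors, config.days,
                               config.arms)
    n_s = len(design)
    n_g = len(genes)

    # fixed draws, in a fixed order, so the truth is reproducible
    base = np.log2(config.baseline_mean) + config.gene_sd * rng.standard_normal(n_g)
    donors = sorted(design["donor"].unique())
    donor_sd_vec = np.full(n_g, config.donor_sd)
    gpos = {g: i for i, g in enumerate(genes)}
    for g in stable:
        donor_sd_vec[gpos[g]] *= config.hk_variance_factor
    donor_off = donor_sd_vec[:, None] * rng.standard_normal((n_g, len(donors)))
    day_wobble = {
        (g, day): config.ref_instability_sd * rng.standard_normal()
        for g in unstable for day in config.days
    }
    lane_log2 = pd.Series(config.lane_sd * rng.standard_normal(n_s),
                          index=design.index)

    deltas = _effect_delta(config, genes)
    donor_col = {d: j for j, d in enumerate(donors)}

    eta = np.empty((n_g, n_s))              # per-sample generative log2 mean
    for j, (sid, row) in enumerate(design.iterrows()):
        cid, day, donor = int(row["condition_id"]), int(row["day"]), int(row["donor"])
        e = base + deltas[(cid, day)] + donor_off[:, donor_col[donor]]
        for g in unstable:
            e[gpos[g]] += day_wobble[(g, day)]
        eta[:, j] = e

    lane = np.exp2(lane_log2.to_numpy())[None, :]
    mu_endo = np.exp2(eta) * lane

    pos = panel.positive_controls
    neg = panel.negative_controls
    mu_pos = np.array([panel.positive_ctrl_inputs[p] for p in pos])[:, None] \
        * config.pos_unit * lane
    mu_neg = np.full((len(neg), n_s), config.neg_mean) * lane

    mu = np.vstack([mu_endo, mu_pos, mu_neg])
    phi = np.concatenate([
        np.where(np.isin(genes, stable),
                 config.dispersion * config.hk_variance_factor,
                 config.dispersion),
        np.full(len(pos) + len(neg), config.ctrl_dispersion),
    ])

    counts = np.rint(mu).astype(np.int64)
    draw = phi > 0
    if draw.any():
        size = 1.0 / phi[draw][:, None]
        p = size / (size + mu[draw])
        counts[draw] = rng.negative_binomial(size, p)

    all_symbols = genes + pos + neg
    values = pd.DataFrame(counts, index=pd.Index(all_symbols, name="symbol"),
                          columns=design.index)
    gene_ann = panel.genes.loc[all_symbols]
    cm = CountMatrix(values, gene_ann, design)

    exp_cols = pd.MultiIndex.from_tuples(sorted(deltas),
                                         names=["condition_id", "day"])
    expected = pd.DataFrame(
        {key: base + deltas[key] for key in sorted(deltas)},
        index=pd.Index(genes, name="symbol"))
    expected.columns = exp_cols
    truth = SimTruth(
        expected_log2=expected,
        effects=list(config.effects),
        stable_references=list(stable),
        lane_log2=lane_log2,
        donor_log2=pd.DataFrame(donor_off, index=pd.Index(genes, name="symbol"),
                                columns=donors),
    )
    return cm, design, truth


def simulate_null_screen(config: SimulationConfig,
                         ) -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """As :func:`simulate_counts` with the planted-effect list forced empty
    (lane, donor and reference-gene structure retained)."""
    return simulate_counts(dataclasses.replace(config, effects=[]))


def _scaled(target: str, term: str, day7: float) -> list[PlantedEffect]:
    """Day-7 effect ``day7`` with the day-1 effect at half strength."""
    half = day7 / 2.0
    return [PlantedEffect(target, term, half, (1, 7)),
            PlantedEffect(target, term, half, (7,))]


def _paper_like_effects() -> list[PlantedEffect]:
    eff: list[PlantedEffect] = []
    # marker-set effects (day-7 magnitudes; day 1 at half strength)
    eff += _scaled("wanted", "TGFB", 0.8)
    eff += _scaled("wanted", "DEX", 0.3)
    eff += _scaled("wanted", "BMP", 0.4)
    eff += _scaled("wanted", "FGF2", -1.0)
    eff += _scaled("wanted", "TGFB:DEX", 1.2)
    eff += _scaled("wanted", "TGFB:BMP", -0.4)
    # unwanted markers rise under TGFB or BMP alone but not beyond either
    # alone in combination, and DEX damps the gain in TGFB conditions
    eff += _scaled("unwanted", "TGFB", 0.4)
    eff += _scaled("unwanted", "BMP", 0.6)
    eff += _scaled("unwanted", "TGFB:BMP", -0.5)
    eff += _scaled("unwanted", "TGFB:DEX", -0.5)
    eff += _scaled("unwanted", "FGF2", -0.6)
    # factor-specific single-gene responses
    eff += _scaled("COL10A1", "TGFB1", 2.0)
    eff += _scaled("BGLAP", "DEX", -2.5)
    eff += _scaled("MMP1", "DEX", -1.5)
    eff += _scaled("MMP7", "DEX", 1.5)
    eff += _scaled("SFRP4", "DEX", -1.5)
    eff += _scaled("SOX9", "TGFB:DEX", 1.0)
    eff += _scaled("NOG", "BMP", 1.5)
    # the broad TGFB-superfamily transcriptional program (drives the
    # TGFB-exposure separation of the screen's PCA)
    for g in design_mod.TGFB_PROGRAM_UP:
        eff += _scaled(g, "TGFB", 1.2)
    for g in design_mod.TGFB_PROGRAM_DOWN:
        eff += _scaled(g, "TGFB", -1.0)
    # unimodal density response of the wanted markers
    eff += _scaled("wanted", "density", 0.3)
    return eff


#: Planted effects of the paper-like preset.
PAPER_LIKE_EFFECTS: tuple[PlantedEffect, ...] = tuple(_paper_like_effects())


def paper_like_config(n_genes: int = 364, seed: int = 0,
                      panel: GenePanel | None = None,
                      registry: ConditionRegistry | None = None,
                      **overrides) -> SimulationConfig:
    """Simulation preset with the planted qualitative screen structure."""
    panel = panel or build_default_panel(n_genes, seed=seed)
    registry = registry or build_condition_registry()
    return SimulationConfig(panel=panel, registry=registry, seed=seed,
                            effects=list(PAPER_LIKE_EFFECTS), **overrides)


def null_config(n_genes: int = 364, seed: int = 0,
                panel: GenePanel | None = None,
                registry: ConditionRegistry | None = None,
                **overrides) -> SimulationConfig:
    """Simulation preset with no planted effects (type-I calibration)."""
    panel = panel or build_default_panel(n_genes, seed=seed)
    registry = registry or build_condition_registry()
    return SimulationConfig(panel=panel, registry=registry, seed=seed,
                            effects=[], **overrides)
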