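"""End-to-end orchestration: config validation, staged run, report bundle.

A run goes simulate (or read) -> normalize -> marker scoring -> factorial
effects -> differential expression (key contrasts, uniform single-factor
genes, overlaps) -> gene-set enrichment -> PCA, fully deterministic for a
given seed.  The single global seed fans out to per-stage substreams so
stage reordering cannot change any stage's stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import CountMatrix, ExpressionMatrix
from .design import (
    FACTORS, ConditionRegistry, GenePanel, build_condition_registry,
    build_default_panel,
)
from .diffexp import (
    BASELINE_CONDITION, ContrastSpec, contrast_de, contrast_overlap,
    fit_genewise_models, uniform_factor_genes,
)
from .effects import FactorialEffects, interaction_summary
from .enrichment import enrichment_table, pca
from .io import read_counts, read_design
from .normalize import normalize_screen
from .scoring import marker_scores, rank_correlation, studentize
from .simulate import null_config, paper_like_config, simulate_counts

__all__ = ["RunConfig", "ReportBundle", "ConfigError", "validate_config",
           "run_screen", "write_bundle", "KEY_CONTRASTS", "stage_seed"]


class ConfigError(ValueError):
    """Configuration file is invalid."""


#: The key condition contrasts of the screen: the effect of adding DEX
#: or BMP2 on top of the strongest backbones.
KEY_CONTRASTS: tuple[ContrastSpec, ...] = (
    ContrastSpec("dex_to_tgfb1", 12, 16, "add DEX to TGFB1"),
    ContrastSpec("dex_to_tgfb1_bmp2", 11, 15, "add DEX to TGFB1+BMP2"),
    ContrastSpec("bmp2_to_tgfb1", 15, 16, "add BMP2 to TGFB1"),
    ContrastSpec("bmp2_to_tgfb1_dex", 11, 12, "add BMP2 to TGFB1+DEX"),
)

_DEFAULTS: dict = {
    "preset": "paper_like",        # paper_like | null | files
    "counts_path": None,
    "design_path": None,
    "panel_path": None,
    "dialect": "tsv",
    "n_genes": 364,
    "n_donors": 3,
    "days": [0, 1, 7],
    "alpha": 0.05,
    "fc_threshold": 1.0,
    "fdr_threshold": 0.05,
    "n_refs": 5,
    "offset_policy": "negctrl",
    "pseudo_count": 0.5,
    "group_by": "day",
    "max_order": 3,
    "day_de": 7,
    "numbering_weights": None,
    "seed": 0,
}

_STAGES = ("simulate", "normalize", "score", "effects", "dge", "enrich", "pca")


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage substream seed derived from the global seed (stable
    under stage reordering; below 2^31)."""
    if stage not in _STAGES:
        raise KeyError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(seed), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration with defaults filled in."""

    preset: str = "paper_like"
    counts_path: str | None = None
    design_path: str | None = None
    panel_path: str | None = None
    dialect: str = "tsv"
    n_genes: int = 364
    n_donors: int = 3
    days: tuple[int, ...] = (0, 1, 7)
    alpha: float = 0.05
    fc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    n_refs: int = 5
    offset_policy: str = "negctrl"
    pseudo_count: float | None = 0.5
    group_by: str = "day"
    max_order: int = 3
    day_de: int = 7
    numbering_weights: dict | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["days"] = list(self.days)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


class _StrictLoader(yaml.SafeLoader):
    """YAML loader that rejects duplicate mapping keys with a line number."""


def _strict_mapping(loader, node, deep=False):
    seen = set()
    for key_node, _ in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in seen:
            raise ConfigError(
                f"duplicate key {key!r} at line {key_node.start_mark.line + 1}")
        seen.add(key)
    return yaml.SafeLoader.construct_mapping(loader, node, deep)


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_mapping)


def validate_config(raw) -> RunConfig:
    """Validate a config mapping, file path or YAML text into a RunConfig."""
    if isinstance(raw, (str, Path)) and Path(str(raw)).exists():
        text = Path(raw).read_text()
        data = yaml.load(text, Loader=_StrictLoader)
    elif isinstance(raw, str):
        data = yaml.load(raw, Loader=_StrictLoader)
    elif raw is None:
        data = {}
    else:
        data = dict(raw)
    data = data or {}
    unknown = set(data) - set(_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    merged = {**_DEFAULTS, **data}
    for key in ("alpha", "fdr_threshold"):
        v = merged[key]
        if not 0 < v < 1:
            raise ConfigError(f"{key}={v} out of range (0, 1)")
    if merged["fc_threshold"] <= 0:
        raise ConfigError("fc_threshold must be positive")
    if merged["n_refs"] < 2:
        raise ConfigError("n_refs must be at least 2")
    if merged["preset"] not in ("paper_like", "null", "files"):
        raise ConfigError(f"unknown preset {merged['preset']!r}")
    merged["days"] = tuple(merged["days"])
    return RunConfig(**merged)


@dataclasses.dataclass
class ReportBundle:
    """All stage outputs of one reproducible screen run."""

    config: RunConfig
    panel: GenePanel
    registry: ConditionRegistry
    design: pd.DataFrame
    counts: CountMatrix
    expression: ExpressionMatrix
    scores: dict[int, pd.DataFrame]
    rank_corr: dict
    effect_tables: dict[str, "object"]
    interactions: dict[str, dict]
    de_results: dict[str, pd.DataFrame]
    uniform_genes: dict[str, dict]
    overlap: dict
    enrichment: pd.DataFrame
    pca_results: dict[str, "object"]
    provenance: dict


def _load_inputs(config: RunConfig):
    registry = build_condition_registry(config.numbering_weights)
    if config.preset == "files":
        if not config.counts_path:
            raise ConfigError("preset 'files' requires counts_path")
        panel = GenePanel.from_tsv(config.panel_path) if config.panel_path else None
        design = read_design(config.design_path) if config.design_path else None
        cm = read_counts(config.counts_path, config.dialect, design, panel)
        if panel is None:
            panel = GenePanel(cm.genes.copy())
        return panel, registry, cm, cm.samples, None
    maker = paper_like_config if config.preset == "paper_like" else null_config
    sim = maker(n_genes=config.n_genes, seed=stage_seed(config.seed, "simulate"),
                registry=registry, n_donors=config.n_donors,
                days=tuple(config.days))
    cm, design, truth = simulate_counts(sim)
    return sim.panel, registry, cm, design, truth


def run_screen(config: RunConfig) -> ReportBundle:
    """Execute the full analysis battery; deterministic per seed."""
    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(
                f"stage {name!r} failed (config {config.config_hash}): {exc}"
            ) from exc

    panel, registry, cm, design, truth = _stage("simulate", _load_inputs, config)
    expr, norm_prov = _stage(
        "normalize", normalize_screen, cm, config.n_refs, config.group_by,
        config.offset_policy, None, config.pseudo_count)

    days_present = sorted(d for d in expr.samples["day"].unique() if d != 0)
    scores = {}
    for day in days_present:
        z = _stage("score", studentize, expr, day)
        scores[day] = marker_scores(z, panel)
    rank_corr = {}
    if {1, 7} <= set(days_present):
        common = scores[1].index.intersection(scores[7].index)
        rank_corr = _stage("score", rank_correlation,
                           scores[1].loc[common], scores[7].loc[common])

    effect_tables = {}
    interactions = {}
    day_eff = config.day_de if config.day_de in days_present else days_present[-1]
    for which in ("wanted", "unwanted"):
        est = FactorialEffects(response=which, day=day_eff,
                               max_order=config.max_order, alpha=config.alpha)
        _stage("effects", est.fit, expr, panel, registry)
        effect_tables[which] = est.effect_table_
        interactions[which] = {
            "TGFB1:DEX": interaction_summary(est.responses_, registry,
                                             ("TGFB1", "DEX")),
            "TGFB1:BMP2": interaction_summary(est.responses_, registry,
                                              ("TGFB1", "BMP2")),
        }

    de_fit = _stage("dge", fit_genewise_models, expr, day_eff)
    de_results = {}
    for spec in KEY_CONTRASTS:
        de_results[spec.name] = _stage(
            "dge", contrast_de, expr, spec, day_eff,
            config.fc_threshold, config.fdr_threshold, fit=de_fit)
    uniform = {}
    for factor in FACTORS:
        uniform[factor] = _stage(
            "dge", uniform_factor_genes, expr, registry, factor, day_eff,
            config.fc_threshold, config.fdr_threshold, fit=de_fit)
    overlap = _stage("dge", contrast_overlap,
                     de_results["dex_to_tgfb1"], de_results["dex_to_tgfb1_bmp2"])

    enrich = _stage("enrich", enrichment_table, expr, registry, panel,
                    day_eff, config.fdr_threshold)

    pca_results = {"all": _stage("pca", pca, expr)}
    for day in days_present:
        mask = (expr.samples["day"] == day) | (expr.samples["day"] == 0)
        mask &= expr.samples["condition_id"].isin(
            registry.factorial_ids + [registry.untreated.id])
        pca_results[f"day{day}"] = _stage(
            "pca", pca, expr.subset_samples(mask))

    provenance = {
        "package": "factoscreen",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "normalization": norm_prov,
    }
    return ReportBundle(
        config=config, panel=panel, registry=registry, design=design,
        counts=cm, expression=expr, scores=scores, rank_corr=rank_corr,
        effect_tables=effect_tables, interactions=interactions,
        de_results=de_results, uniform_genes=uniform, overlap=overlap,
        enrichment=enrich, pca_results=pca_results, provenance=provenance)


def write_bundle(bundle: ReportBundle, out_dir) -> None:
    """Write every report table of a bundle as TSV plus provenance JSON.

    Output is byte-identical across runs with the same config and seed
    (no timestamps, sorted keys).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.registry.to_tsv(out / "conditions.tsv")
    bundle.panel.to_tsv(out / "panel.tsv")
    bundle.design.to_csv(out / "design.tsv", sep="\t")
    bundle.expression.values.to_csv(out / "expression.tsv", sep="\t")
    for day, table in bundle.scores.items():
        table.to_csv(out / f"scores_day{day}.tsv", sep="\t",
                     index_label="condition_id")
    for which, et in bundle.effect_tables.items():
        et.table.to_csv(out / f"effects_{which}.tsv", sep="\t",
                        index_label="term")
        et.normal_plot.to_csv(out / f"normalplot_{which}.tsv", sep="\t")
    for name, res in bundle.de_results.items():
        res.to_csv(out / f"dge_{name}.tsv", sep="\t", index_label="gene")
    bundle.enrichment.to_csv(out / "enrichment.tsv", sep="\t")
    for name, pr in bundle.pca_results.items():
        pr.scores.to_csv(out / f"pca_{name}_scores.tsv", sep="\t",
                         index_label="sample_id")
        pd.Series(pr.explained_variance_ratio).to_csv(
            out / f"pca_{name}_variance.tsv", sep="\t", header=["fraction"])
    report = {
        "rank_correlation": bundle.rank_corr,
        "uniform_genes": bundle.uniform_genes,
        "overlap": {k: v for k, v in bundle.overlap.items()
                    if not k.startswith("genes")},
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "provenance.json").write_text(
        json.dumps(bundle.provenance, indent=2, sort_keys=True, default=str))
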