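"""Shared fixtures: small simulated screens and their normalized form."""

import numpy as np
import pandas as pd
import pytest

import factoscreen as fs
from factoscreen.containers import ExpressionMatrix
from factoscreen.simulate import paper_like_config, simulate_counts


@pytest.fixture(scope="session")
def registry():
    return fs.build_condition_registry()


@pytest.fixture(scope="session")
def panel_small():
    return fs.build_default_panel(120, seed=7)


@pytest.fixture(scope="session")
def screen_small(registry, panel_small):
    """One paper-like screen on a 120-gene panel (3 donors, days 0/1/7)."""
    cfg = paper_like_config(panel=panel_small, registry=registry, seed=11)
    cm, design, truth = simulate_counts(cfg)
    return cfg, cm, design, truth


@pytest.fixture(scope="session")
def expr_small(screen_small):
    cfg, cm, design, truth = screen_small
    expr, prov = fs.normalize_screen(cm)
    return expr, prov


def make_expression(values: pd.DataFrame, conditions, donors, days,
                    marker_sets=None) -> ExpressionMatrix:
    """Hand-build a tiny ExpressionMatrix for unit tests."""
    samples = pd.DataFrame({
        "condition_id": conditions, "donor": donors, "day": days,
        "lane": np.arange(1, len(conditions) + 1),
    }, index=values.columns)
    genes = pd.DataFrame({
        "cls": "endogenous",
        "marker_set": [marker_sets.get(g, "other") if marker_sets else "other"
                       for g in values.index],
    }, index=values.index)
    return ExpressionMatrix(values.astype(float), genes, samples)
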