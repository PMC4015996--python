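"""Gene-wise contrasts, variance moderation, BH and consistency analyses."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import factoscreen as fs
from factoscreen.diffexp import (
    BASELINE_CONDITION, ContrastSpec, GenewiseFit, ModerationParams,
    bh_adjust, call_de, contrast_de, contrast_overlap,
    fit_genewise_contrast, fit_genewise_models, moderate_variance,
    squeeze_variances, uniform_factor_genes,
)
from factoscreen.simulate import (
    PlantedEffect, SimulationConfig, simulate_counts,
)
from .conftest import make_expression


def paired_expr(a_vals, b_vals, genes=("g1",)):
    """Expression with conditions 12 (A) and 16 (B), three donors."""
    vals = pd.DataFrame(
        np.concatenate([a_vals, b_vals]).reshape(len(genes), -1),
        index=list(genes), columns=[f"s{i}" for i in range(6)])
    return make_expression(vals, [12, 12, 12, 16, 16, 16],
                           [1, 2, 3, 1, 2, 3], [7] * 6)


class TestGenewiseFit:
    def test_constant_replicates_give_exact_fc_zero_variance(self):
        expr = paired_expr([7.0, 7.0, 7.0], [5.0, 5.0, 5.0])
        spec = ContrastSpec("t", 12, 16)
        fit = fit_genewise_contrast(expr, spec, day=7)
        assert fit.loc["g1", "log2fc"] == pytest.approx(2.0)
        assert fit.loc["g1", "s2"] == pytest.approx(0.0)
        pooled = fit_genewise_models(expr, day=7)
        assert pooled.fc(12, 16)["g1"] == pytest.approx(2.0)
        assert pooled.s2["g1"] == pytest.approx(0.0, abs=1e-20)

    def test_swapping_conditions_negates_fc(self):
        rng = np.random.default_rng(0)
        expr = paired_expr(rng.normal(7, 1, 3), rng.normal(5, 1, 3))
        ab = fit_genewise_contrast(expr, ContrastSpec("f", 12, 16), 7)
        ba = fit_genewise_contrast(expr, ContrastSpec("r", 16, 12), 7)
        assert ab["log2fc"]["g1"] == pytest.approx(-ba["log2fc"]["g1"])
        assert ab["s2"]["g1"] == pytest.approx(ba["s2"]["g1"])

    def test_pooled_model_matches_pairwise_on_two_conditions(self):
        rng = np.random.default_rng(1)
        expr = paired_expr(rng.normal(7, 1, 3), rng.normal(5, 1, 3))
        pair = fit_genewise_contrast(expr, ContrastSpec("f", 12, 16), 7)
        pooled = fit_genewise_models(expr, day=7)
        assert pooled.fc(12, 16)["g1"] == pytest.approx(pair["log2fc"]["g1"])
        assert pooled.s2["g1"] == pytest.approx(pair["s2"]["g1"])
        assert pooled.df == pair["df"]["g1"]

    def test_missing_replicates_rejected(self):
        vals = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        expr = make_expression(vals, [12, 16], [1, 1], [7, 7])
        with pytest.raises(Exception, match="replicate"):
            fit_genewise_contrast(expr, ContrastSpec("t", 12, 16), 7)

    def test_planted_fold_change_recovered(self, registry):
        panel = fs.build_default_panel(60, seed=0)
        ests = []
        for seed in range(10):
            cfg = SimulationConfig(
                panel=panel, registry=registry, n_donors=3, days=(7,),
                arms=("factorial",), dispersion=0.05,
                effects=[PlantedEffect("COL2A1", "DEX", 1.5, (7,))],
                seed=seed)
            cm, _, _ = simulate_counts(cfg)
            expr, _ = fs.normalize_screen(cm)
            fit = fit_genewise_models(expr, day=7)
            ests.append(fit.fc(28, 32)["COL2A1"])    # DEX alone vs baseline
        assert abs(np.mean(ests) - 1.5) < 0.2


class TestModeration:
    def test_identical_variances_hit_infinite_prior(self):
        from scipy.special import digamma
        s2 = np.full(50, 0.3)
        params, s2_tilde = moderate_variance(s2, df=4)
        assert np.isinf(params.d0)
        assert np.allclose(s2_tilde, params.s02)
        # moment estimator applies the chi^2 log-bias correction to s0^2
        expected = 0.3 * np.exp(np.log(2.0) - digamma(2.0))
        assert params.s02 == pytest.approx(expected, rel=1e-10)

    def test_zero_prior_df_returns_raw_variances(self):
        s2 = np.array([0.1, 0.5, 2.0, 4.0])
        out = squeeze_variances(s2, df=4, params=ModerationParams(0.0, 1.0))
        assert np.allclose(out, s2)

    def test_infinite_prior_df_returns_prior_variance(self):
        s2 = np.array([0.1, 0.5, 2.0])
        out = squeeze_variances(s2, df=4,
                                params=ModerationParams(float("inf"), 0.7))
        assert np.allclose(out, 0.7)

    def test_posterior_between_prior_and_observed(self):
        s2 = np.array([0.01, 1.0, 9.0])
        params = ModerationParams(4.0, 1.0)
        out = squeeze_variances(s2, df=4, params=params)
        assert np.all((out - s2) * (out - params.s02) <= 1e-12)

    def test_hyperparameter_recovery_from_scaled_inv_chi2(self):
        """d0=4, s0^2=0.05 recovered from 2000 sampled variances."""
        d0s, s02s = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            df, d0, s02 = 4, 4.0, 0.05
            sigma2 = s02 * d0 / rng.chisquare(d0, 2000)
            s2 = sigma2 * rng.chisquare(df, 2000) / df
            params, _ = moderate_variance(s2, df)
            d0s.append(params.d0)
            s02s.append(params.s02)
        assert 3.0 <= np.mean(d0s) <= 5.3
        assert abs(np.mean(s02s) - 0.05) / 0.05 < 0.2

    def test_matches_limma_squeeze_var(self, tmp_path):
        """Independent oracle: limma::squeezeVar on the same variances."""
        rng = np.random.default_rng(42)
        df = 4
        sigma2 = 0.1 * 5.0 / rng.chisquare(5.0, 400)
        s2 = sigma2 * rng.chisquare(df, 400) / df
        np.savetxt(tmp_path / "s2.txt", s2)
        script = (
            f's2 <- scan("{tmp_path}/s2.txt"); '
            f'suppressMessages(library(limma)); '
            f'fit <- squeezeVar(s2, df={df}); '
            f'cat(fit$df.prior, fit$var.prior, fit$var.post[1], '
            f'fit$var.post[100], sep="\\n")')
        res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        r_d0, r_s02, r_post1, r_post100 = map(float, res.stdout.split())
        params, s2_tilde = moderate_variance(s2, df)
        assert params.d0 == pytest.approx(r_d0, rel=0.02)
        assert params.s02 == pytest.approx(r_s02, rel=0.02)
        assert s2_tilde[0] == pytest.approx(r_post1, rel=0.02)
        assert s2_tilde[99] == pytest.approx(r_post100, rel=0.02)


def brute_force_bh(p):
    p = np.asarray(p, float)
    m = len(p)
    q = np.empty(m)
    for i, pi in enumerate(p):
        # q_i = min over all thresholds t >= p_i of t*m/rank(t)
        cands = []
        for pj in p:
            if pj >= pi:
                rank = (p <= pj).sum()
                cands.append(min(1.0, pj * m / rank))
        q[i] = min(cands)
    return q


class TestBH:
    def test_hand_worked_example(self):
        q = bh_adjust([0.005, 0.011, 0.02, 0.04])
        assert np.allclose(q, [0.02, 0.022, 0.0266667, 0.04], atol=1e-6)

    def test_single_and_tied_p_values(self):
        assert bh_adjust([0.031])[0] == pytest.approx(0.031)
        assert np.allclose(bh_adjust([0.03] * 5), 0.03)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(seed=st.integers(0, 10_000), m=st.integers(1, 60))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_definition(self, seed, m):
        p = np.random.default_rng(seed).uniform(size=m)
        assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=200)
            ours = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, theirs, atol=1e-12)


class TestCallDE:
    def test_fold_change_rule(self):
        res = pd.DataFrame({"log2fc": [0.9, 2.0], "q": [0.001, 0.049]},
                           index=["a", "b"])
        out = call_de(res)
        assert not out.loc["a", "significant"]      # below twofold
        assert out.loc["b", "significant"]
        assert out.loc["b", "direction"] == "up"

    def test_constructed_truth_counts(self):
        rng = np.random.default_rng(1)
        fcs = np.concatenate([[2.0, -3.0, 1.5], rng.uniform(-0.5, 0.5, 7)])
        qs = np.concatenate([[0.001, 0.01, 0.02], rng.uniform(0.2, 1.0, 7)])
        out = call_de(pd.DataFrame({"log2fc": fcs, "q": qs}))
        assert int(out["significant"].sum()) == 3


class TestUniformFactorGenes:
    def _screen(self, registry, effects, seed=0):
        panel = fs.build_default_panel(60, seed=1)
        cfg = SimulationConfig(
            panel=panel, registry=registry, n_donors=3, days=(7,),
            arms=("factorial",), dispersion=0.02, effects=effects, seed=seed)
        cm, _, _ = simulate_counts(cfg)
        expr, _ = fs.normalize_screen(cm)
        return expr

    def test_gene_down_in_all_factor_conditions_is_reported(self, registry):
        expr = self._screen(registry,
                            [PlantedEffect("BGLAP", "DEX", -2.5, (7,))])
        out = uniform_factor_genes(expr, registry, "DEX", day=7)
        assert "BGLAP" in out["down"]
        assert out["n_conditions"] == 16

    def test_gene_missing_one_condition_is_excluded(self, registry):
        # null in the all-factors condition only: 15 of 16 is not enough
        expr = self._screen(registry, [
            PlantedEffect("BGLAP", "DEX", -2.5, (7,)),
            PlantedEffect("BGLAP", "TGFB1:FGF2:DEX:IGF1:BMP2", 2.5, (7,)),
        ])
        out = uniform_factor_genes(expr, registry, "DEX", day=7)
        assert "BGLAP" not in out["down"]

    def test_direction_flip_is_excluded(self, registry):
        # up without BMP2, down with BMP2: consistent in neither direction
        expr = self._screen(registry, [
            PlantedEffect("BGLAP", "DEX", 2.5, (7,)),
            PlantedEffect("BGLAP", "DEX:BMP2", -5.0, (7,)),
        ])
        out = uniform_factor_genes(expr, registry, "DEX", day=7)
        assert "BGLAP" not in out["down"]
        assert "BGLAP" not in out["up"]

    def test_unknown_factor_rejected(self, expr_small, registry):
        expr, _ = expr_small
        with pytest.raises(KeyError, match="EGF"):
            uniform_factor_genes(expr, registry, "EGF")


class TestOverlap:
    def _result(self, genes, sig, direction="up"):
        return pd.DataFrame({
            "log2fc": [2.0 if d == "up" else -2.0 for d in direction],
            "significant": sig, "direction": direction,
        }, index=genes) if isinstance(direction, list) else pd.DataFrame({
            "log2fc": 2.0, "significant": sig, "direction": direction,
        }, index=genes)

    def test_counted_intersection(self):
        genes = [f"g{i}" for i in range(8)]
        a = self._result(genes, [True] * 5 + [False] * 3, "up")
        b = self._result(genes, [False] * 2 + [True] * 5 + [False], "up")
        out = contrast_overlap(a, b)
        assert out["n_a"] == 5 and out["n_b"] == 5
        assert out["n_overlap"] == 3

    def test_self_overlap_is_total(self):
        genes = [f"g{i}" for i in range(6)]
        a = self._result(genes, [True, True, False, True, False, False], "up")
        out = contrast_overlap(a, a)
        assert out["n_overlap"] == out["n_a"] == out["n_b"] == 3

    def test_opposite_directions_not_counted(self):
        genes = ["g1", "g2"]
        a = self._result(genes, [True, True], ["up", "up"])
        b = self._result(genes, [True, True], ["up", "down"])
        out = contrast_overlap(a, b)
        assert out["n_overlap"] == 1

    def test_mismatched_universes_rejected(self):
        a = self._result(["g1"], [True], "up")
        b = self._result(["g2"], [True], "up")
        with pytest.raises(ValueError, match="universe"):
            contrast_overlap(a, b)


class TestContrastDE:
    def test_moderated_battery_on_simulated_screen(self, expr_small, registry):
        expr, _ = expr_small
        res = contrast_de(expr, ContrastSpec("dex_to_tgfb1", 12, 16), day=7)
        assert res["q"].between(0, 1).all()
        assert res.attrs["moderation"].d0 > 0
        # planted synergy targets change when DEX is added to TGFB1
        assert res.loc["BGLAP", "significant"]
        assert res.loc["BGLAP", "direction"] == "down"

    def test_null_screen_calls_almost_nothing(self, registry):
        panel = fs.build_default_panel(60, seed=2)
        cfg = SimulationConfig(panel=panel, registry=registry, n_donors=3,
                               days=(7,), arms=("factorial",), effects=[],
                               seed=5)
        cm, _, _ = simulate_counts(cfg)
        expr, _ = fs.normalize_screen(cm)
        res = contrast_de(expr, ContrastSpec("null", 11, 12), day=7)
        assert res["significant"].mean() <= 0.05
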