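"""Normalization chain: I/O, lane factors, stability model, glog."""

import numpy as np
import pandas as pd
import pytest

import factoscreen as fs
from factoscreen.containers import CountMatrix, ValidationError
from factoscreen.io import ParseError, read_counts, write_counts, write_design
from factoscreen.normalize import (
    NormalizationError, glog, glog_transform, lane_scale_factors,
    normfinder_stability, reference_normalize, select_references,
)
from factoscreen.simulate import paper_like_config, simulate_counts


class TestIO:
    @pytest.mark.parametrize("dialect", ["rcc_like", "tsv"])
    def test_round_trip(self, tmp_path, screen_small, dialect):
        cfg, cm, design, _ = screen_small
        path = tmp_path / f"counts.{dialect}"
        write_counts(cm, path, dialect=dialect)
        back = read_counts(path, dialect=dialect, design=design,
                           panel=cfg.panel)
        assert back.values.equals(cm.values)
        assert back.genes.equals(cm.genes)

    def test_cross_dialect_equivalence(self, tmp_path, screen_small):
        cfg, cm, design, _ = screen_small
        write_counts(cm, tmp_path / "a.csv", dialect="rcc_like")
        write_counts(cm, tmp_path / "b.tsv", dialect="tsv")
        a = read_counts(tmp_path / "a.csv", "rcc_like", design, cfg.panel)
        b = read_counts(tmp_path / "b.tsv", "tsv", design, cfg.panel)
        assert a.values.equals(b.values)
        assert a.genes.equals(b.genes)

    def test_negative_count_names_gene_and_sample(self, tmp_path):
        (tmp_path / "bad.csv").write_text(
            "Sample,s1,lane,1\nEndogenous,ACAN,-3\n")
        with pytest.raises(ValidationError, match="ACAN.*s1"):
            read_counts(tmp_path / "bad.csv", "rcc_like")

    def test_unknown_class_code(self, tmp_path):
        (tmp_path / "bad.csv").write_text(
            "Sample,s1,lane,1\nMystery,ACAN,3\n")
        with pytest.raises(ParseError, match="Mystery"):
            read_counts(tmp_path / "bad.csv", "rcc_like")

    def test_annotation_round_trip_without_panel(self, tmp_path, screen_small):
        cfg, cm, design, _ = screen_small
        write_counts(cm, tmp_path / "c.tsv", dialect="tsv")
        back = read_counts(tmp_path / "c.tsv", "tsv", design=design)
        assert list(back.genes["cls"]) == list(cm.genes["cls"])


def toy_counts(values: np.ndarray, classes: list[str]) -> CountMatrix:
    n_g, n_s = values.shape
    syms = [f"G{i}" for i in range(n_g)]
    genes = pd.DataFrame({"cls": classes, "marker_set": "other"},
                         index=pd.Index(syms, name="symbol"))
    samples = pd.DataFrame(
        {"condition_id": range(1, n_s + 1), "donor": 1, "day": 7,
         "lane": range(1, n_s + 1)},
        index=pd.Index([f"s{i}" for i in range(n_s)], name="sample_id"))
    vals = pd.DataFrame(values, index=genes.index, columns=samples.index)
    return CountMatrix(vals, genes, samples, require_int=False)


class TestLaneFactors:
    def test_identical_controls_give_unit_factors(self):
        cm = toy_counts(np.full((3, 4), 50.0), ["positive_ctrl"] * 3)
        f = lane_scale_factors(cm)
        assert np.allclose(f, 1.0)

    def test_halved_sample_gets_factor_two(self):
        vals = np.full((3, 4), 80.0)
        vals[:, 2] /= 2
        cm = toy_counts(vals, ["positive_ctrl"] * 3)
        f = lane_scale_factors(cm)
        # the grand mean shifts by 2^(-1/4); relative factor is exactly 2
        assert f.iloc[2] / f.iloc[0] == pytest.approx(2.0, rel=1e-12)
        scaled = cm.values * f
        assert np.allclose(np.exp(np.log(scaled).mean(0)),
                           np.exp(np.log(scaled).mean(0)).iloc[0])

    def test_zero_control_requires_pseudo_count(self):
        vals = np.full((2, 3), 40.0)
        vals[0, 1] = 0
        cm = toy_counts(vals, ["positive_ctrl"] * 2)
        with pytest.raises(NormalizationError, match="pseudo-count"):
            lane_scale_factors(cm)
        assert lane_scale_factors(cm, pseudo_count=0.5).notna().all()

    def test_recovers_simulated_lane_effects(self, registry):
        """log lane factors track the planted lognormal lane effects."""
        panel = fs.build_default_panel(40, seed=0)
        rs = []
        for seed in range(10):
            cfg = paper_like_config(panel=panel, registry=registry, seed=seed,
                                    n_donors=1, days=(7,), lane_sd=0.2)
            cm, _, truth = simulate_counts(cfg)
            f = lane_scale_factors(cm, pseudo_count=0.5)
            rs.append(np.corrcoef(np.log2(f), -truth.lane_log2)[0, 1])
        assert np.mean(rs) >= 0.95


class TestNormFinder:
    def test_zero_variance_zero_bias_candidate_ranks_first(self):
        rng = np.random.default_rng(0)
        n = 10
        groups = pd.Series(["a"] * n + ["b"] * n,
                           index=[f"s{i}" for i in range(2 * n)])
        e = rng.normal(0, 0.3, 2 * n)
        # remove group structure so every d is exactly zero after centering,
        # and mirror the noise so the estimated sample effects are exact
        for block in (slice(0, n), slice(n, 2 * n)):
            e[block] -= e[block].mean()
        data = pd.DataFrame(
            np.vstack([np.full(2 * n, 5.0), 8.0 + e, 8.0 - e]),
            index=["stable", "n1", "n2"], columns=groups.index)
        table = normfinder_stability(data, groups)
        assert table.loc["stable", "rho"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["stable", "rank"] == 1

    def test_single_group_reduces_to_residual_variance_ranking(self):
        rng = np.random.default_rng(1)
        sds = [0.05, 0.4, 0.1, 0.25]
        n = 30
        sample_eff = rng.normal(0, 0.5, n)
        data = pd.DataFrame(
            [5.0 + sample_eff + rng.normal(0, sd, n) for sd in sds],
            index=[f"c{i}" for i in range(4)],
            columns=[f"s{i}" for i in range(n)])
        groups = pd.Series("only", index=data.columns)
        table = normfinder_stability(data, groups)
        # independent oracle: residual variance of the additive model
        resid = data.to_numpy()
        resid = resid - resid.mean(1, keepdims=True) \
            - resid.mean(0, keepdims=True) + resid.mean()
        oracle_order = np.argsort((resid ** 2).sum(1))
        assert list(table.sort_values("rank").index) == \
            [f"c{i}" for i in oracle_order]
        assert (table.filter(like="d[").abs().to_numpy() == 0).all()

    def test_stability_rank_tracks_injected_noise(self):
        """Candidates with more added noise must rank less stable."""
        sds = [0.02, 0.1, 0.2, 0.3, 0.4, 0.5]
        rhos = []
        from scipy.stats import spearmanr
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 20
            cols = [f"s{i}" for i in range(2 * n)]
            groups = pd.Series(["d1"] * n + ["d7"] * n, index=cols)
            sample_eff = rng.normal(0, 0.4, 2 * n)
            data = pd.DataFrame(
                [6.0 + sample_eff + rng.normal(0, sd, 2 * n) for sd in sds],
                index=[f"c{i}" for i in range(len(sds))], columns=cols)
            table = normfinder_stability(data, groups)
            rho, _ = spearmanr(table["rho"].loc[[f"c{i}" for i in range(6)]],
                               sds)
            rhos.append(rho)
        assert np.mean(rhos) >= 0.9

    def test_requires_three_candidates_and_two_per_group(self):
        data = pd.DataFrame(np.ones((2, 4)), index=["a", "b"],
                            columns=[f"s{i}" for i in range(4)])
        groups = pd.Series(["x", "x", "y", "y"], index=data.columns)
        with pytest.raises(NormalizationError, match="3 candidate"):
            normfinder_stability(data, groups)
        data3 = pd.DataFrame(np.ones((3, 3)), index=["a", "b", "c"],
                             columns=[f"s{i}" for i in range(3)])
        groups3 = pd.Series(["x", "x", "y"], index=data3.columns)
        with pytest.raises(NormalizationError, match="fewer than 2"):
            normfinder_stability(data3, groups3)


class TestSelectReferences:
    def test_counts_and_ties(self):
        table = pd.DataFrame({"rho": [0.2, 0.1, 0.2, 0.05]},
                             index=["B", "Z", "A", "M"])
        table = table.loc[sorted(table.index)]
        table["rank"] = pd.Series(
            range(1, 5),
            index=table.sort_values("rho", kind="mergesort").index)
        assert select_references(table, 3) == ["M", "Z", "A"]
        assert len(select_references(table, 4)) == 4
        with pytest.raises(ValueError):
            select_references(table, 5)


class TestReferenceNormalize:
    def test_already_equal_references_leave_matrix_unchanged(self):
        vals = np.vstack([np.full((2, 4), 100.0),
                          np.arange(8, dtype=float).reshape(2, 4) + 1])
        cm = toy_counts(vals, ["housekeeping_candidate"] * 2 + ["endogenous"] * 2)
        out = reference_normalize(cm, ["G0", "G1"])
        assert np.allclose(out.values, cm.values)

    def test_scaled_sample_divided_back_exactly(self):
        """A x4 sample is divided by 4 relative to the others; the grand
        geometric-mean target shifts all samples by the common 4^(1/n)."""
        rng = np.random.default_rng(2)
        vals = rng.integers(50, 500, (5, 4)).astype(float)
        cm = toy_counts(vals, ["housekeeping_candidate"] * 3 + ["endogenous"] * 2)
        vals4 = vals.copy()
        vals4[:, 1] *= 4
        cm4 = toy_counts(vals4, ["housekeeping_candidate"] * 3 + ["endogenous"] * 2)
        out = reference_normalize(cm, ["G0", "G1", "G2"])
        out4 = reference_normalize(cm4, ["G0", "G1", "G2"])
        ratio = (out4.values / out.values).to_numpy()
        assert np.allclose(ratio, 4.0 ** 0.25, rtol=1e-12)

    def test_post_condition_equal_geometric_means(self, screen_small):
        cfg, cm, _, _ = screen_small
        refs = cfg.panel.housekeeping_candidates[:5]
        out = reference_normalize(cm, refs, pseudo_count=0.5)
        gm = np.exp(np.log(out.values.loc[refs]).mean(0))
        assert np.allclose(gm, gm.iloc[0], rtol=1e-12)


class TestGlog:
    def test_closed_forms(self):
        assert glog(0.0, 7.0) == pytest.approx(np.log2(3.5))
        assert abs(glog(2.0 ** 20, 10.0) - 20.0) < 1e-4

    def test_strictly_increasing(self):
        x = np.linspace(0, 1000, 500)
        h = glog(x, 12.0)
        assert (np.diff(h) > 0).all()

    def test_variance_flattening_versus_plain_log(self):
        """glog equalizes replicate sds of low- and high-count genes."""
        rng = np.random.default_rng(5)
        phi, n = 0.05, 400
        draws = {}
        for mu in (5.0, 5000.0):
            size = 1 / phi
            draws[mu] = rng.negative_binomial(size, size / (size + mu), n)
        c = 10.0
        ratio_glog = glog(draws[5.0], c).std() / glog(draws[5000.0], c).std()
        ratio_plain = np.log2(draws[5.0] + 1.0).std() \
            / np.log2(draws[5000.0] + 1.0).std()
        assert ratio_glog < 3.0
        assert ratio_glog < ratio_plain

    def test_fixed_policy_requires_positive_c(self, screen_small):
        _, cm, _, _ = screen_small
        with pytest.raises(ValueError, match="c > 0"):
            glog_transform(cm, offset_policy="fixed", c=0.0)

    def test_below_background_flag_present(self, screen_small):
        _, cm, _, _ = screen_small
        expr = glog_transform(cm)
        assert "below_background" in expr.genes.columns


class TestFullChain:
    def test_equivariance_to_global_sample_rescaling(self, screen_small):
        """Rescaling one sample's counts shifts every normalized value by
        one common constant (log2(alpha)/n via the grand means); profile
        shapes are unchanged to 1e-10."""
        cfg, cm, _, _ = screen_small
        expr, _ = fs.normalize_screen(cm)
        scaled = CountMatrix(cm.values.copy(), cm.genes, cm.samples,
                             require_int=False)
        sid = scaled.values.columns[5]
        scaled.values[sid] *= 3.0
        expr2, _ = fs.normalize_screen(scaled)
        delta = (expr2.values - expr.values).to_numpy()
        shift = np.log2(3.0) / cm.values.shape[1]
        assert np.allclose(delta, shift, atol=1e-10)

    def test_housekeeping_truth_recovered(self, registry):
        """>=4 of the 5 selected references are truly stable in >=90% of
        seeds under the default preset."""
        panel = fs.build_default_panel(80, seed=0)
        hits = 0
        for seed in range(20):
            cfg = paper_like_config(panel=panel, registry=registry, seed=seed)
            cm, _, truth = simulate_counts(cfg)
            _, prov = fs.normalize_screen(cm)
            overlap = len(set(prov["references"])
                          & set(truth.stable_references))
            hits += overlap >= 4
        assert hits >= 18

    def test_provenance_records_parameters(self, expr_small):
        expr, prov = expr_small
        assert len(prov["references"]) == 5
        assert prov["glog_c"] > 0
        assert expr.meta["references"] == prov["references"]
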