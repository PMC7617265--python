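import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import transwalker as tw
from transwalker.association import classify_pair_category, meta_fixed
from transwalker.synthetic import CELL_TYPES, generate_eqtm_scenario


def frame(arr, prefix="f"):
    arr = np.atleast_2d(np.asarray(arr, float))
    return pd.DataFrame(arr.T if arr.shape[0] < arr.shape[1] else arr,
                        index=[f"s{i}" for i in range(max(arr.shape))],
                        columns=[f"{prefix}{j}" for j in range(min(arr.shape))])


class TestResidualize:
    def test_intercept_only_centres(self):
        rng = np.random.default_rng(0)
        y = pd.DataFrame(rng.normal(5, 2, (20, 3)),
                         index=[f"s{i}" for i in range(20)])
        cov = pd.DataFrame(index=y.index)
        res = tw.residualize(y, cov, [])
        assert np.allclose(res.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(res, y - y.mean(axis=0))

    def test_outcome_as_own_covariate_gives_zero(self):
        rng = np.random.default_rng(1)
        y = pd.DataFrame({"y": rng.normal(size=15)},
                         index=[f"s{i}" for i in range(15)])
        cov = pd.DataFrame({"same": y["y"]}, index=y.index)
        res = tw.residualize(y, cov, ["same"])
        assert np.allclose(res, 0, atol=1e-10)

    def test_residuals_orthogonal_to_design(self):
        # normal-equations oracle: X'r = 0 for OLS residuals
        rng = np.random.default_rng(2)
        y = pd.DataFrame(rng.normal(size=(10, 4)),
                         index=[f"s{i}" for i in range(10)])
        cov = pd.DataFrame(rng.normal(size=(10, 3)), index=y.index,
                           columns=["a", "b", "c"])
        res = tw.residualize(y, cov, ["a", "b", "c"])
        x = np.column_stack([np.ones(10), cov.to_numpy()])
        xs = (x - x.mean(0)) / np.where(x.std(0) == 0, 1, x.std(0))
        assert np.abs(xs.T @ res.to_numpy()).max() < 1e-8 * 10

    def test_collinear_design_named(self):
        rng = np.random.default_rng(3)
        y = pd.DataFrame(rng.normal(size=(12, 1)),
                         index=[f"s{i}" for i in range(12)])
        cov = pd.DataFrame({"a": rng.normal(size=12)}, index=y.index)
        cov["double_a"] = 2 * cov["a"]
        with pytest.raises(ValueError, match="double_a"):
            tw.residualize(y, cov, ["a", "double_a"])


class TestQtlScan:
    def test_five_point_toy_matches_hand_ols(self):
        g = pd.DataFrame({"g": [0, 0, 1, 1, 2]},
                         index=[f"s{i}" for i in range(5)], dtype=float)
        y = pd.DataFrame({"y": [1, 1, 2, 2, 3]}, index=g.index, dtype=float)
        rec = tw.qtl_scan(g, y).iloc[0]
        assert rec["beta"] == pytest.approx(1.0, abs=1e-12)

    def test_perfect_fit_underflows_p(self):
        g = pd.DataFrame({"g": np.arange(50, dtype=float)},
                         index=[f"s{i}" for i in range(50)])
        y = 0.5 * g.rename(columns={"g": "y"})
        rec = tw.qtl_scan(g, y).iloc[0]
        assert rec["beta"] == pytest.approx(0.5, abs=1e-10)
        assert rec["log10p"] < -250

    def test_matches_statsmodels_closed_form(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        g = pd.DataFrame(rng.integers(0, 3, size=(30, 2)).astype(float),
                         index=[f"s{i}" for i in range(30)], columns=["a", "b"])
        y = pd.DataFrame(rng.normal(size=(30, 2)), index=g.index,
                         columns=["u", "v"])
        scan = tw.qtl_scan(g, y)
        for _, rec in scan.iterrows():
            fit = sm.OLS(y[rec["target"]],
                         sm.add_constant(g[rec["source"]])).fit()
            assert rec["beta"] == pytest.approx(fit.params.iloc[1], abs=1e-10)
            assert rec["se"] == pytest.approx(fit.bse.iloc[1], abs=1e-10)
            assert rec["p"] == pytest.approx(fit.pvalues.iloc[1], rel=1e-8)

    def test_zero_variance_predictor_flagged_not_dropped(self):
        g = pd.DataFrame({"flat": np.ones(10), "ok": np.arange(10.0)},
                         index=[f"s{i}" for i in range(10)])
        y = pd.DataFrame({"y": np.random.default_rng(0).normal(size=10)},
                         index=g.index)
        scan = tw.qtl_scan(g, y)
        assert len(scan) == 2
        assert bool(scan.set_index("source").loc["flat", "untestable"])
        assert not bool(scan.set_index("source").loc["ok", "untestable"])

    def test_permutation_calibration_under_planted_effect(self):
        rng = np.random.default_rng(7)
        n, m = 200, 2000
        g = rng.integers(0, 3, size=(n, m)).astype(float)
        y = 0.5 * g + rng.normal(size=(n, m))
        perm = rng.permutation(n)
        gp = pd.DataFrame(g[perm], index=[f"s{i}" for i in range(n)])
        yd = pd.DataFrame(y, index=gp.index)
        pairs = [(j, j) for j in range(m)]
        scan = tw.qtl_scan(gp, yd, pairs=pairs)
        frac = (scan["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / m)
        assert abs(frac - 0.05) < 3 * se


class TestCategories:
    @pytest.mark.parametrize("snp,cpg,expected", [
        (("chr1", 1_000), ("chr1", 500_000), "cis"),
        (("chr1", 1_000), ("chr1", 2_500_000), "long_range_cis"),
        (("chr1", 1_000), ("chr2", 1_000), "trans"),
        (("chr1", 0), ("chr1", 1_000_000), "long_range_cis"),  # strict <1Mb
        (("chr1", 0), ("chr1", 999_999), "cis"),
    ])
    def test_distance_rules(self, snp, cpg, expected):
        srow = {"chrom": snp[0], "start": snp[1]}
        crow = {"chrom": cpg[0], "start": cpg[1]}
        assert classify_pair_category(srow, crow) == expected

    def test_missing_annotation_raises(self):
        with pytest.raises(ValueError, match="annotation"):
            classify_pair_category({"chrom": "chr1"}, {"chrom": "chr1",
                                                       "start": 5})

    def test_every_pair_gets_exactly_one_category(self, scenario):
        scan = tw.qtl_scan(scenario["dosages"].iloc[:, :5],
                           scenario["methylation"].iloc[:, :5])
        out = tw.classify_records(scan, scenario["snp_anno"],
                                  scenario["cpg_anno"])
        assert out["category"].isin(["cis", "long_range_cis", "trans"]).all()


class TestMeta:
    def test_equal_records_closed_form(self):
        b, s, p = meta_fixed([1.0, 1.0], [1.0, 1.0])
        assert b == pytest.approx(1.0)
        assert s == pytest.approx(1 / np.sqrt(2), abs=1e-9)

    def test_opposite_effects_cancel(self):
        b, _, _ = meta_fixed([1.0, -1.0], [1.0, 1.0])
        assert b == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_unequal_weights(self):
        # weights 1 and 0.25: beta = (2 + 0)/1.25 = 1.6, se = 2/sqrt(5)
        b, s, _ = meta_fixed([2.0, 0.0], [1.0, 2.0])
        assert b == pytest.approx(1.6, abs=1e-12)
        assert s == pytest.approx(2 / np.sqrt(5), abs=1e-12)

    def test_k_identical_records_shrink_se_by_sqrt_k(self):
        for k in (2, 3, 5):
            _, s, _ = meta_fixed([0.7] * k, [0.3] * k)
            assert s == pytest.approx(0.3 / np.sqrt(k), abs=1e-12)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            meta_fixed([1.0, 1.0], [1.0, 0.0])

    @given(beta=st.floats(-10, 10), se=st.floats(0.01, 5),
           k=st.integers(2, 8))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_identical_record_property(self, beta, se, k):
        """k identical cohorts: effect unchanged, se shrinks by sqrt(k)."""
        b, s, _ = meta_fixed([beta] * k, [se] * k)
        assert b == pytest.approx(beta, rel=1e-9, abs=1e-12)
        assert s == pytest.approx(se / np.sqrt(k), rel=1e-9)

    def test_frame_meta_se_below_min_cohort(self):
        d = pd.DataFrame({"source": ["a"], "target": ["b"], "beta": [0.5],
                          "se": [0.1], "p": [1e-6], "n": [100]})
        r = pd.DataFrame({"source": ["a"], "target": ["b"], "beta": [0.4],
                          "se": [0.2], "p": [0.04], "n": [100]})
        meta = tw.meta_analyse([d, r])
        assert meta["se"].iloc[0] <= 0.1


class TestReplicationFilter:
    def _frames(self, b_disc, p_disc, b_rep, p_rep):
        from scipy.stats import norm
        z_d = norm.isf(p_disc / 2)
        z_r = norm.isf(p_rep / 2)
        d = pd.DataFrame({"source": ["a"], "target": ["b"], "beta": [b_disc],
                          "se": [abs(b_disc) / z_d], "p": [p_disc], "n": [500]})
        r = pd.DataFrame({"source": ["a"], "target": ["b"], "beta": [b_rep],
                          "se": [abs(b_rep) / z_r], "p": [p_rep], "n": [500]})
        return d, r

    def test_all_criteria_met_passes(self):
        d, r = self._frames(0.5, 1e-20, 0.4, 0.01)
        assert bool(tw.replication_filter(d, r)["replicated"].iloc[0])

    def test_opposite_sign_fails_despite_tiny_p(self):
        d, r = self._frames(0.5, 1e-20, -0.5, 1e-20)
        assert not bool(tw.replication_filter(d, r)["replicated"].iloc[0])

    def test_weak_replication_p_fails(self):
        d, r = self._frames(0.5, 1e-20, 0.1, 0.2)
        assert not bool(tw.replication_filter(d, r)["replicated"].iloc[0])


class TestInteractionScan:
    def _toy(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        g = pd.DataFrame({"g": rng.integers(0, 3, n).astype(float)}, index=idx)
        c = pd.Series(rng.normal(size=n), index=idx, name="ctx")
        return g, c, idx

    def test_pure_interaction_underflows(self):
        g, c, idx = self._toy()
        y = pd.DataFrame({"y": g["g"] * c}, index=idx)
        rec = tw.interaction_scan(g, y, c).iloc[0]
        assert rec["log10p"] < -100

    def test_matches_four_column_lstsq_oracle(self):
        g, c, idx = self._toy(seed=3)
        rng = np.random.default_rng(4)
        y = pd.DataFrame({"y": 0.2 * g["g"] + 0.1 * c
                          + 0.3 * g["g"] * c + rng.normal(size=len(idx))},
                         index=idx)
        rec = tw.interaction_scan(g, y, c).iloc[0]
        x = np.column_stack([np.ones(len(idx)), g["g"], c, g["g"] * c])
        coef, *_ = np.linalg.lstsq(x, y["y"].to_numpy(), rcond=None)
        resid = y["y"].to_numpy() - x @ coef
        sigma2 = resid @ resid / (len(idx) - 4)
        se = np.sqrt(sigma2 * np.linalg.inv(x.T @ x)[3, 3])
        t = coef[3] / se
        p = 2 * stats.t.sf(abs(t), len(idx) - 4)
        assert rec["beta"] == pytest.approx(coef[3], abs=1e-10)
        assert rec["se"] == pytest.approx(se, abs=1e-10)
        assert rec["p"] == pytest.approx(p, rel=1e-8)

    def test_degenerate_design_flagged(self):
        g, _, idx = self._toy()
        c = pd.Series(np.ones(len(idx)), index=idx)  # g*c == g
        y = pd.DataFrame({"y": np.random.default_rng(1).normal(size=len(idx))},
                         index=idx)
        rec = tw.interaction_scan(g, y, c).iloc[0]
        assert bool(rec["untestable"])

    def test_null_interaction_calibrated(self):
        rng = np.random.default_rng(11)
        n, m = 200, 400
        idx = [f"s{i}" for i in range(n)]
        g = pd.DataFrame(rng.integers(0, 3, (n, m)).astype(float), index=idx)
        c = pd.Series(rng.normal(size=n), index=idx)
        y = pd.DataFrame(0.3 * g.to_numpy() + rng.normal(size=(n, m)), index=idx)
        scan = tw.interaction_scan(g, y, c, pairs=[(j, j) for j in range(m)])
        frac = (scan["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / m)


class TestEqtmScan:
    def test_cell_adjustment_removes_confounding_keeps_direct(self):
        data = generate_eqtm_scenario(seed=2)
        meth, expr, cells = (data["methylation"], data["expression"],
                             data["cells"])
        raw = tw.eqtm_scan(meth, expr, pairs=[("cg_conf", "gene_conf"),
                                              ("cg_direct", "gene_direct")])
        adj = tw.eqtm_scan(meth, expr, pairs=[("cg_conf", "gene_conf"),
                                              ("cg_direct", "gene_direct")],
                           adjust_cells=True, cell_proportions=cells)
        raw = raw.set_index("source")
        adj = adj.set_index("source")
        assert raw.loc["cg_conf", "p"] < 1e-4       # confounded looks real
        assert adj.loc["cg_conf", "p"] > 0.05       # adjustment removes it
        assert adj.loc["cg_direct", "p"] < 1e-4     # direct effect survives

    def test_zero_variance_proportions_equal_unadjusted(self):
        data = generate_eqtm_scenario(seed=4)
        meth, expr = data["methylation"], data["expression"]
        flat = data["cells"].copy()
        flat.loc[:, :] = 0.2
        raw = tw.eqtm_scan(meth, expr)
        adj = tw.eqtm_scan(meth, expr, adjust_cells=True,
                           cell_proportions=flat)
        pd.testing.assert_frame_equal(raw, adj)

    def test_missing_cell_columns_rejected(self):
        data = generate_eqtm_scenario(seed=5)
        with pytest.raises(ValueError, match="missing"):
            tw.eqtm_scan(data["methylation"], data["expression"],
                         adjust_cells=True,
                         cell_proportions=data["cells"][["CD8T"]])
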