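"""PGLS, type-II tests, post-hocs, partial correlation, GVIF and dredging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import sharkpcm as sp
from sharkpcm.regression import (DesignSpec, Term, aicc_penalty, dredge_aicc,
                                 fit_pgls, gvif, partial_correlation,
                                 posthoc_pairwise, type2_anova)
from sharkpcm.trees import phylo_covariance


@pytest.fixture(scope="module")
def tree60():
    return sp.simulate_yule_tree(60, 1.0, seed=21)


@pytest.fixture(scope="module")
def cov60(tree60):
    return phylo_covariance(tree60)


class TestPglsCore:
    def test_lambda_zero_equals_textbook_ols(self, tree60):
        for seed in range(5):
            d = sp.simulate_pgls_dataset(tree60, {"x": 0.4}, 0.5, 1.0,
                                         {"x": "bm", "w": "iid"}, seed=seed)
            spec = DesignSpec("y", (Term("x"), Term("w")))
            fit = fit_pgls(tree60, d, spec, lambda_mode=0.0)
            X = np.column_stack([np.ones(len(d)), d["x"], d["w"]])
            beta = np.linalg.solve(X.T @ X, X.T @ d["y"].to_numpy())
            np.testing.assert_allclose(fit.params["coef"].to_numpy(), beta, atol=1e-10)

    def test_profile_maximizer_is_reported_lambda(self, tree60):
        d = sp.simulate_pgls_dataset(tree60, {"x": 0.4}, 0.6, 1.0, {"x": "bm"}, seed=3)
        fit = fit_pgls(tree60, d, DesignSpec("y", (Term("x"),)))
        prof = fit.profile
        assert prof is not None and len(prof) == 101
        # the refined optimum cannot be worse than any grid point
        assert fit.lnl >= prof["lnl"].max() - 1e-8
        assert abs(fit.lambda_ - prof.loc[prof["lnl"].idxmax(), "lambda"]) <= 0.011

    def test_singular_design_names_aliased_columns(self, tree60):
        d = sp.simulate_pgls_dataset(tree60, {}, 0.5, 1.0, {"x": "bm"}, seed=4)
        d["x2"] = 2 * d["x"]
        with pytest.raises(ValueError, match="x2"):
            fit_pgls(tree60, d, DesignSpec("y", (Term("x"), Term("x2"))))

    def test_outlier_flagging(self, tree60):
        d = sp.simulate_pgls_dataset(tree60, {"x": 0.4}, 0.0, 0.05, {"x": "iid"}, seed=5)
        victim = d.index[7]
        d.loc[victim, "y"] += 5.0
        fit = fit_pgls(tree60, d, DesignSpec("y", (Term("x"),)), lambda_mode=0.0)
        assert victim in fit.outliers

    def test_aicc_consistent_with_definition(self, tree60):
        d = sp.simulate_pgls_dataset(tree60, {"x": 0.4}, 0.5, 1.0, {"x": "bm"}, seed=6)
        fit = fit_pgls(tree60, d, DesignSpec("y", (Term("x"),)))
        k = len(fit.params)
        aic = 2 * k - 2 * fit.lnl
        assert fit.aicc == pytest.approx(aic + aicc_penalty(k, fit.n))

    def test_aicc_penalty_example(self):
        assert aicc_penalty(2, 5) == pytest.approx(6.0)


class TestTypeII:
    def test_orthogonal_design_equals_sequential(self, tree60):
        # balanced orthogonal predictors: drop-one SS equals sequential SS
        rng = np.random.default_rng(0)
        n = 60
        x = np.tile([-1.0, 1.0], 30)
        w = np.repeat([-1.0, 1.0], 30)
        d = pd.DataFrame({"x": x, "w": w, "y": 0.5 * x + 0.2 * w + rng.normal(0, 1, n)},
                         index=sp.trees.tip_labels(tree60))
        fit = fit_pgls(tree60, d, DesignSpec("y", (Term("x"), Term("w"))), lambda_mode=0.0)
        an = type2_anova(fit)
        # sequential (type I) oracle via RSS differences in fitting order
        def rss(cols):
            X = np.column_stack([np.ones(n)] + [d[c].to_numpy() for c in cols])
            b = np.linalg.lstsq(X, d["y"].to_numpy(), rcond=None)[0]
            return float(((d["y"].to_numpy() - X @ b) ** 2).sum())

        rss_full = rss(["x", "w"])
        ms = rss_full / (n - 3)
        f_x_seq = (rss([]) - rss(["x"])) / ms
        f_w_seq = (rss(["x"]) - rss_full) / ms
        assert an.loc["x", "F"] == pytest.approx(f_x_seq, rel=1e-6)
        assert an.loc["w", "F"] == pytest.approx(f_w_seq, rel=1e-6)

    def test_hand_built_rss_ratio(self):
        tree = sp.simulate_yule_tree(8, 1.0, seed=30)
        labels = sp.trees.tip_labels(tree)
        d = pd.DataFrame({"x": [1, 2, 3, 4, 5, 6, 7, 8.0],
                          "y": [2.1, 2.0, 3.5, 3.9, 5.2, 5.0, 6.8, 7.1]}, index=labels)
        fit = fit_pgls(tree, d, DesignSpec("y", (Term("x"),)), lambda_mode=0.0)
        an = type2_anova(fit)
        X_full = np.column_stack([np.ones(8), d["x"]])
        b = np.linalg.lstsq(X_full, d["y"], rcond=None)[0]
        rss_f = float(((d["y"] - X_full @ b) ** 2).sum())
        rss_r = float(((d["y"] - d["y"].mean()) ** 2).sum())
        F = (rss_r - rss_f) / (rss_f / 6)
        assert an.loc["x", "F"] == pytest.approx(F, rel=1e-8)
        assert an.loc["x", "df_den"] == 6


class TestPosthoc:
    def test_bh_adjustment_hand_example(self):
        adj = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.04])

    def test_two_level_factor_single_comparison(self, tree60):
        d = sp.simulate_pgls_dataset(tree60, {"f[b]": 0.8}, 0.3, 0.5,
                                     {"f": ("categorical", ["a", "b"], [0.5, 0.5])}, seed=7)
        spec = DesignSpec("y", (Term("f", categorical=True),))
        ph = posthoc_pairwise(tree60, d, spec, "f")
        assert len(ph) == 1
        assert ph["p_adj"].iloc[0] == pytest.approx(ph["p_raw"].iloc[0])

    def test_all_pairs_present_and_monotone(self, tree60):
        d = sp.simulate_pgls_dataset(
            tree60, {"f[b]": 1.0, "f[c]": -0.5}, 0.3, 0.5,
            {"f": ("categorical", ["a", "b", "c"], [0.4, 0.3, 0.3])}, seed=8)
        spec = DesignSpec("y", (Term("f", categorical=True),))
        ph = posthoc_pairwise(tree60, d, spec, "f")
        assert len(ph) == 3
        assert (ph["p_adj"] >= ph["p_raw"] - 1e-12).all()

    def test_releveled_contrast_matches_coefficient_difference(self, tree60):
        d = sp.simulate_pgls_dataset(
            tree60, {"f[b]": 1.0, "f[c]": -0.5}, 0.0, 0.5,
            {"f": ("categorical", ["a", "b", "c"], [0.4, 0.3, 0.3])}, seed=9)
        spec = DesignSpec("y", (Term("f", categorical=True),))
        fit = fit_pgls(tree60, d, spec, lambda_mode=0.0)
        ph = posthoc_pairwise(tree60, d, spec, "f", lambda_mode=0.0)
        bc = ph[(ph.level_a == "b") & (ph.level_b == "c")]["estimate"].iloc[0]
        expect = fit.params.loc["f[c]", "coef"] - fit.params.loc["f[b]", "coef"]
        assert bc == pytest.approx(expect, abs=1e-8)


class TestPartialCorrelation:
    def test_orthogonal_covariate_keeps_slope(self, tree60):
        d = sp.simulate_pgls_dataset(tree60, {"x": 0.6}, 0.0, 0.3,
                                     {"x": "iid", "c": "iid"}, seed=10)
        simple = fit_pgls(tree60, d, DesignSpec("y", (Term("x"),)), lambda_mode=0.0)
        part = partial_correlation(tree60, d, "y", "x", "c", lambda_mode=0.0)
        assert part.params.loc["resid_x", "coef"] == pytest.approx(
            simple.params.loc["x", "coef"], abs=0.1)

    def test_pure_confound_gives_zero_partial_slope(self, tree60):
        rng = np.random.default_rng(1)
        c = rng.normal(size=60)
        d = pd.DataFrame({"c": c, "x": c + rng.normal(0, 0.1, 60), "y": 2.0 * c},
                         index=sp.trees.tip_labels(tree60))
        part = partial_correlation(tree60, d, "y", "x", "c", lambda_mode=0.0)
        assert abs(part.params.loc["resid_x", "coef"]) < 0.05

    def test_identical_covariate_rejected(self, tree60):
        d = sp.simulate_pgls_dataset(tree60, {}, 0.0, 1.0, {"x": "iid"}, seed=11)
        with pytest.raises(ValueError, match="identical"):
            partial_correlation(tree60, d, "y", "x", "x")


class TestDredge:
    def test_constrained_enumeration_hand_example(self, tree60):
        d = sp.simulate_pgls_dataset(tree60, {"A": 0.5, "L": 0.3}, 0.3, 0.5,
                                     {"L": "bm", "A": "bm", "B": "iid", "C": "iid"}, seed=12)
        spec = DesignSpec("y", (Term("L"), Term("A"), Term("B"), Term("C")))
        res = dredge_aicc(tree60, d, spec, fixed=("L",), forbidden_pairs=[("A", "B")])
        got = {frozenset(t) for t in res.models["terms"]}
        expect = {frozenset(s) for s in [("L",), ("L", "A"), ("L", "B"), ("L", "C"),
                                         ("L", "A", "C"), ("L", "B", "C")]}
        assert got == expect
        assert res.models["weight"].sum() == pytest.approx(1.0)
        assert res.models["delta"].min() == 0.0
        assert len(res.best) >= 1

    def test_true_model_ranks_in_best_set(self, tree60):
        hits = 0
        for seed in range(12):
            d = sp.simulate_pgls_dataset(tree60, {"A": 1.2, "L": 0.8}, 0.4, 0.3,
                                         {"L": "bm", "A": "bm", "B": "iid", "C": "iid"},
                                         seed=100 + seed)
            spec = DesignSpec("y", (Term("L"), Term("A"), Term("B"), Term("C")))
            res = dredge_aicc(tree60, d, spec, fixed=("L",))
            best_sets = [set(t) for t in res.best["terms"]]
            if any({"L", "A"} <= s for s in best_sets):
                hits += 1
        assert hits >= 10  # >= 80% of replicates with strong effects

    def test_fixed_covariate_in_every_model(self, tree60):
        d = sp.simulate_pgls_dataset(tree60, {"L": 0.5}, 0.3, 0.5,
                                     {"L": "bm", "A": "iid"}, seed=13)
        spec = DesignSpec("y", (Term("L"), Term("A")))
        res = dredge_aicc(tree60, d, spec, fixed=("L",))
        assert all("L" in t for t in res.models["terms"])

    def test_gvif_near_one_for_orthogonal_predictors(self, tree60):
        rng = np.random.default_rng(2)
        d = pd.DataFrame({"a": rng.normal(size=60), "b": rng.normal(size=60),
                          "y": rng.normal(size=60)}, index=sp.trees.tip_labels(tree60))
        g = gvif(d, DesignSpec("y", (Term("a"), Term("b"))))
        assert g["gvif_scaled"].max() < 1.3

    def test_gvif_flags_collinear_pair(self, tree60):
        rng = np.random.default_rng(3)
        a = rng.normal(size=60)
        d = pd.DataFrame({"a": a, "b": a + rng.normal(0, 0.05, 60),
                          "y": rng.normal(size=60)}, index=sp.trees.tip_labels(tree60))
        g = gvif(d, DesignSpec("y", (Term("a"), Term("b"))))
        assert g["gvif_scaled"].max() > 2.0


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=12))
def test_bh_adjustment_monotone_and_at_least_raw(ps):
    adj = multipletests(ps, method="fdr_bh")[1]
    order = np.argsort(ps)
    assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)
    assert np.all(adj >= np.asarray(ps) - 1e-12)
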