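"""Regression-layer tests against independently coded matrix-algebra oracles."""

import types

import numpy as np
import pandas as pd
import pytest

from equitarget.exceptions import (
    ClusteringError,
    DegenerateMarginError,
    NoTurningPointError,
    SeparationError,
    SingularDesignError,
    ValidationError,
)
from equitarget.panel import (
    ModelSpec,
    TargetingModel,
    detect_rollout_year,
    fit_by_region,
    fit_ols_fe,
    fit_quadratic,
    fit_two_part,
    turning_point,
    vif,
    wald_equality_test,
    year_by_year,
)


def cr1_oracle(y, X, clusters, weights=None):
    """Normal equations + clustered sandwich, written from the formulas.

    Returns (beta, se) with the CR1 small-sample factor
    G/(G-1) * (N-1)/(N-K) and no reliance on the fitting code under test.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, k = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    Xw = X * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    u = yw - Xw @ beta
    meat = np.zeros((k, k))
    for g in np.unique(clusters):
        sel = np.asarray(clusters) == g
        s = Xw[sel].T @ u[sel]
        meat += np.outer(s, s)
    G = len(np.unique(clusters))
    c = G / (G - 1) * (n - 1) / (n - k)
    bread = np.linalg.inv(XtX)
    V = c * bread @ meat @ bread
    return beta, np.sqrt(np.diag(V))


def build_random_panel(seed=0, n_areas=8, years=(2018, 2019)):
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_areas):
        x = rng.uniform(0.2, 2.5)
        for y in years:
            rows.append(
                {
                    "area_id": f"a{a}",
                    "region": "R1" if a < n_areas // 2 else "R2",
                    "year": y,
                    "relative_cni": x,
                    "dosage": 0.05 + 0.1 * x + rng.normal(0, 0.05),
                    "n_households": int(rng.integers(20, 90)),
                }
            )
    return pd.DataFrame(rows)


SPEC = ModelSpec(outcome="dosage", predictors=("relative_cni",))


class TestFitOlsFe:
    def test_matches_cr1_oracle(self, toy_panel):
        res = fit_ols_fe(toy_panel, SPEC)
        X = np.column_stack(
            [
                np.ones(len(toy_panel)),
                toy_panel["relative_cni"],
                (toy_panel["year"] == 2019).astype(float),
            ]
        )
        beta, se = cr1_oracle(toy_panel["dosage"], X, toy_panel["area_id"])
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-10)
        np.testing.assert_allclose(res.bse.to_numpy(), se, atol=1e-10)

    def test_matches_cr1_oracle_weighted(self, toy_panel):
        spec = ModelSpec(
            outcome="dosage", predictors=("relative_cni",), weights_by="n_households"
        )
        res = fit_ols_fe(toy_panel, spec)
        X = np.column_stack(
            [
                np.ones(len(toy_panel)),
                toy_panel["relative_cni"],
                (toy_panel["year"] == 2019).astype(float),
            ]
        )
        beta, se = cr1_oracle(
            toy_panel["dosage"], X, toy_panel["area_id"], toy_panel["n_households"]
        )
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-10)
        np.testing.assert_allclose(res.bse.to_numpy(), se, atol=1e-10)

    def test_noise_free_line_recovered_exactly(self):
        df = pd.DataFrame(
            {
                "area_id": list("abcdef"),
                "year": 2020,
                "relative_cni": [0.2, 0.5, 1.0, 1.5, 2.0, 2.5],
            }
        )
        df["dosage"] = 0.1 * df["relative_cni"]
        res = fit_ols_fe(df, ModelSpec(outcome="dosage", predictors=("relative_cni",), fixed_effects=()))
        assert res.params["relative_cni"] == pytest.approx(0.1, abs=1e-12)
        assert np.abs(res.resid).max() < 1e-12

    def test_year_fe_absorbs_year_shift(self):
        df = build_random_panel(seed=1)
        base = fit_ols_fe(df, SPEC).params["relative_cni"]
        shifted = df.copy()
        shifted.loc[shifted["year"] == 2019, "dosage"] += 0.37
        after = fit_ols_fe(shifted, SPEC).params["relative_cni"]
        assert after == pytest.approx(base, abs=1e-12)

    def test_residuals_sum_to_zero(self):
        df = build_random_panel(seed=2, n_areas=30)
        res = fit_ols_fe(df, SPEC)
        scale = np.abs(df["dosage"]).sum()
        assert abs(res.resid.sum()) < 1e-8 * scale

    def test_singleton_clusters_reduce_to_hc_times_factor(self):
        df = build_random_panel(seed=3, n_areas=20, years=(2020,))
        res = fit_ols_fe(df, ModelSpec(outcome="dosage", predictors=("relative_cni",), fixed_effects=()))
        X = np.column_stack([np.ones(len(df)), df["relative_cni"]])
        beta = np.linalg.solve(X.T @ X, X.T @ df["dosage"])
        u = df["dosage"].to_numpy() - X @ beta
        bread = np.linalg.inv(X.T @ X)
        hc0 = bread @ (X * u[:, None] ** 2).T @ X @ bread
        n, k = X.shape
        factor = n / (n - 1) * (n - 1) / (n - k)
        np.testing.assert_allclose(
            res.bse.to_numpy(), np.sqrt(factor * np.diag(hc0)), atol=1e-12
        )

    def test_row_order_and_cluster_label_invariance(self):
        df = build_random_panel(seed=4, n_areas=12)
        res = fit_ols_fe(df, SPEC)
        shuffled = df.sample(frac=1, random_state=5).reset_index(drop=True)
        shuffled["area_id"] = "zz_" + shuffled["area_id"]
        res2 = fit_ols_fe(shuffled, SPEC)
        np.testing.assert_allclose(res.params, res2.params, atol=1e-12)
        np.testing.assert_allclose(res.bse, res2.bse, atol=1e-12)

    def test_single_cluster_raises(self):
        df = build_random_panel(seed=6, n_areas=4)
        df["area_id"] = "same"
        with pytest.raises(ClusteringError):
            fit_ols_fe(df, SPEC)

    def test_rank_deficiency_names_terms(self):
        df = build_random_panel(seed=7)
        df["copy_of_need"] = df["relative_cni"]
        spec = ModelSpec(outcome="dosage", predictors=("relative_cni", "copy_of_need"))
        with pytest.raises(SingularDesignError, match="copy_of_need|relative_cni"):
            fit_ols_fe(df, spec)

    def test_outcome_in_predictors_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec(outcome="dosage", predictors=("dosage",))


class TestQuadraticAndTurningPoint:
    def test_pure_line_gives_null_quadratic(self):
        rng = np.random.default_rng(8)
        df = build_random_panel(seed=8, n_areas=60)
        df["dosage"] = 0.02 + 0.1 * df["relative_cni"] + rng.normal(0, 0.02, len(df))
        res = fit_quadratic(df, SPEC)
        assert abs(res.params["relative_cni_sq"]) < 0.02
        assert res.nonlinearity_wald.pvalue > 0.05

    def test_exact_quadratic_turning_point(self):
        x = np.linspace(0.0, 2.0, 41)
        df = pd.DataFrame(
            {
                "area_id": [f"a{i}" for i in range(41)],
                "year": 2020,
                "relative_cni": x,
                "dosage": (x - 0.49) ** 2,
            }
        )
        res = fit_quadratic(df, ModelSpec(outcome="dosage", predictors=("relative_cni",), fixed_effects=()))
        tp = turning_point(res, need_values=x)
        assert tp.value == pytest.approx(0.49, abs=1e-6)
        assert tp.share_above == pytest.approx((x > 0.49).mean())

    def test_binary_need_square_collinear(self):
        df = build_random_panel(seed=9, n_areas=20)
        df["relative_cni"] = (df["relative_cni"] > 1).astype(float)
        with pytest.raises(SingularDesignError):
            fit_quadratic(df, SPEC)

    def test_closed_form_and_degenerate(self):
        fake = types.SimpleNamespace(params=pd.Series({"b1": -0.049, "b2": 0.05}))
        tp = turning_point(fake, "b1", "b2")
        assert tp.value == pytest.approx(0.49, abs=1e-12)
        zero_b1 = types.SimpleNamespace(params=pd.Series({"b1": 0.0, "b2": 0.05}))
        assert turning_point(zero_b1, "b1", "b2").value == 0.0
        flat = types.SimpleNamespace(params=pd.Series({"b1": 0.1, "b2": 0.0}))
        with pytest.raises(NoTurningPointError):
            turning_point(flat, "b1", "b2")


class TestRegionalFits:
    def test_duplicated_regions_identical_coefficients(self):
        df = build_random_panel(seed=10, n_areas=10)
        df["region"] = "R1"
        dup = df.copy()
        dup["region"] = "R2"
        dup["area_id"] = "dup_" + dup["area_id"]
        both = pd.concat([df, dup], ignore_index=True)
        fits = fit_by_region(both, SPEC)
        np.testing.assert_allclose(
            fits.fits["R1"].params, fits.fits["R2"].params, atol=1e-12
        )

    def test_region_with_one_area_skipped_with_warning(self):
        df = build_random_panel(seed=11, n_areas=10)
        solo = df.iloc[:2].copy()
        solo["region"] = "R9"
        solo["area_id"] = "only_one"
        both = pd.concat([df, solo], ignore_index=True)
        with pytest.warns(UserWarning, match="R9"):
            fits = fit_by_region(both, SPEC)
        assert fits.skipped == ["R9"]
        assert "R9" not in fits.fits


class TestWaldEqualityTest:
    def test_equal_slopes_interaction_vanishes_noise_free(self):
        df = build_random_panel(seed=12, n_areas=20)
        df["dosage"] = 0.03 + 0.1 * df["relative_cni"]
        # the pooled interaction coefficient itself must be numerically zero
        d = df.copy()
        d["r2"] = (d["region"] == "R2").astype(float)
        d["x_r2"] = d["relative_cni"] * d["r2"]
        spec = ModelSpec(outcome="dosage", predictors=("relative_cni", "r2", "x_r2"))
        res = fit_ols_fe(d, spec)
        assert abs(res.params["x_r2"]) < 1e-10
        w = wald_equality_test(df, SPEC)
        assert w.df == 1

    def test_equal_slopes_with_noise_not_rejected(self):
        rng = np.random.default_rng(12)
        df = build_random_panel(seed=12, n_areas=40)
        df["dosage"] = 0.03 + 0.1 * df["relative_cni"] + rng.normal(0, 0.03, len(df))
        w = wald_equality_test(df, SPEC)
        assert w.pvalue > 0.05

    def test_matches_brute_force_quadratic_form(self):
        df = build_random_panel(seed=13, n_areas=10)
        w = wald_equality_test(df, SPEC)
        # oracle: build the pooled interaction design by hand, CR1 sandwich,
        # then the quadratic form on the interaction coefficient
        d = df.copy()
        d["r2"] = (d["region"] == "R2").astype(float)
        d["x_r2"] = d["relative_cni"] * d["r2"]
        X = np.column_stack(
            [
                np.ones(len(d)),
                d["relative_cni"],
                d["r2"],
                d["x_r2"],
                (d["year"] == 2019).astype(float),
            ]
        )
        beta, _ = cr1_oracle(d["dosage"], X, d["area_id"])
        # full covariance for the quadratic form
        n, k = X.shape
        u = d["dosage"].to_numpy() - X @ beta
        meat = np.zeros((k, k))
        for g_ in np.unique(d["area_id"]):
            sel = (d["area_id"] == g_).to_numpy()
            s = X[sel].T @ u[sel]
            meat += np.outer(s, s)
        G = d["area_id"].nunique()
        c = G / (G - 1) * (n - 1) / (n - k)
        bread = np.linalg.inv(X.T @ X)
        V = c * bread @ meat @ bread
        stat = beta[3] ** 2 / V[3, 3]
        assert w.statistic == pytest.approx(stat, abs=1e-10 * max(1, stat))

    def test_pvalue_in_unit_interval(self):
        for seed in range(3):
            df = build_random_panel(seed=seed, n_areas=12)
            w = wald_equality_test(df, SPEC)
            assert 0.0 <= w.pvalue <= 1.0


def irls_logit_oracle(y, X, tol=1e-12, maxiter=200):
    """Independent iteratively-reweighted least-squares logistic fit."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        p = 1 / (1 + np.exp(-eta))
        W = p * (1 - p)
        z = eta + (y - p) / W
        new = np.linalg.solve(X.T @ (X * W[:, None]), X.T @ (W * z))
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta


class TestTwoPart:
    def test_log_odds_match_irls_oracle(self):
        df = build_random_panel(seed=14, n_areas=40)
        df["dosage"] = (df["dosage"] > df["dosage"].median()).astype(float) * df["dosage"]
        res = fit_two_part(df, SPEC, logit_fixed_effects=False)
        X = np.column_stack([np.ones(len(df)), df["relative_cni"]])
        oracle = irls_logit_oracle((df["dosage"] > 0).to_numpy(float), X)
        np.testing.assert_allclose(res.extensive.params.to_numpy(), oracle, atol=1e-8)

    def test_intensive_n_equals_nonzero_count(self):
        rng = np.random.default_rng(15)
        df = build_random_panel(seed=15, n_areas=40)
        df["dosage"] = df["dosage"].abs() * rng.binomial(1, 0.6, len(df))
        res = fit_two_part(df, SPEC)
        assert res.intensive.nobs == int((df["dosage"] > 0).sum())

    def test_all_positive_outcome_raises(self):
        df = build_random_panel(seed=16, n_areas=10)
        df["dosage"] = df["dosage"].abs() + 0.01
        with pytest.raises(DegenerateMarginError):
            fit_two_part(df, SPEC)

    def test_null_need_gives_odds_ratio_near_one(self):
        rng = np.random.default_rng(17)
        n = 4000
        df = pd.DataFrame(
            {
                "area_id": [f"a{i}" for i in range(n)],
                "year": 2020,
                "relative_cni": rng.uniform(0, 3, n),
                "dosage": rng.binomial(1, 0.3, n) * rng.random(n),
            }
        )
        res = fit_two_part(df, SPEC, logit_fixed_effects=False)
        orr = res.extensive.odds_ratios["relative_cni"]
        lo, hi = res.extensive.conf_int().loc["relative_cni"]
        assert lo < 1.0 < hi or abs(orr - 1) < 0.15

    def test_perfect_separation_raises(self):
        df = build_random_panel(seed=18, n_areas=40)
        df["dosage"] = (df["relative_cni"] > 1.2).astype(float) * 0.3
        with pytest.raises(SeparationError):
            fit_two_part(df, SPEC, logit_fixed_effects=False)


class TestYearByYear:
    def test_single_year_equals_plain_cross_section(self):
        df = build_random_panel(seed=19, n_areas=15, years=(2020,))
        yearly = year_by_year(df, SPEC)
        plain = fit_ols_fe(df, ModelSpec(outcome="dosage", predictors=("relative_cni",), fixed_effects=()))
        np.testing.assert_allclose(yearly[2020].params, plain.params, atol=1e-12)

    def test_sparse_year_skipped_with_warning(self):
        df = build_random_panel(seed=20, n_areas=10)
        extra = df.iloc[:1].copy()
        extra["year"] = 2030
        both = pd.concat([df, extra], ignore_index=True)
        with pytest.warns(UserWarning, match="2030"):
            yearly = year_by_year(both, SPEC)
        assert 2030 not in yearly


class TestRolloutDetection:
    def _panel(self, shares_by_year):
        rows = []
        n = 25
        for year, share in shares_by_year:
            k = round(share * n)
            for i in range(n):
                rows.append(
                    {
                        "area_id": f"a{i}",
                        "region": "R1",
                        "year": year,
                        "dosage": 0.2 if i < k else 0.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_threshold_crossing_year(self):
        panel = self._panel([(2018, 0.0), (2019, 0.08), (2020, 0.12)])
        assert detect_rollout_year(panel, threshold=0.10) == {"R1": 2020}

    def test_never_reached_is_none(self):
        panel = self._panel([(2018, 0.0), (2019, 0.0)])
        assert detect_rollout_year(panel, threshold=0.10) == {"R1": None}

    def test_zero_threshold_first_positive_year(self):
        panel = self._panel([(2018, 0.0), (2019, 0.04), (2020, 0.5)])
        assert detect_rollout_year(panel, threshold=0.0) == {"R1": 2019}

    def test_invalid_threshold(self):
        with pytest.raises(ValidationError):
            detect_rollout_year(self._panel([(2018, 0.5)]), threshold=1.5)


class TestVif:
    def test_single_predictor_is_one(self):
        df = build_random_panel(seed=21)
        assert vif(df, ["relative_cni"]) == {"relative_cni": 1.0}

    def test_orthogonal_predictors(self):
        n = 64
        df = pd.DataFrame(
            {"a": np.tile([1.0, -1.0], n // 2), "b": np.repeat([1.0, -1.0], n // 2)}
        )
        out = vif(df, ["a", "b"])
        assert out["a"] == pytest.approx(1.0, abs=1e-12)
        assert out["b"] == pytest.approx(1.0, abs=1e-12)

    def test_two_predictor_closed_form(self):
        rng = np.random.default_rng(22)
        a = rng.normal(size=500)
        b = 0.6 * a + 0.8 * rng.normal(size=500)
        df = pd.DataFrame({"a": a, "b": b})
        r = np.corrcoef(a, b)[0, 1]
        expected = 1 / (1 - r**2)
        out = vif(df, ["a", "b"])
        assert out["a"] == pytest.approx(expected, abs=1e-10)
        assert out["b"] == pytest.approx(expected, abs=1e-10)

    def test_perfect_collinearity_flagged_inf(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        out = vif(df, ["a", "b"])
        assert out["a"] == np.inf and out["b"] == np.inf
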