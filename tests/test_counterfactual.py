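"""OLS and robust log TFR ~ CPR fits and the counterfactual quantities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avert import counterfactual as cf
from avert.errors import EstimationError


def districts_on_line(cpr, beta0=1.199, beta1=-0.0083, noise=None, births=1000.0):
    cpr = np.asarray(cpr, float)
    log_tfr = beta0 + beta1 * cpr + (0 if noise is None else noise)
    return pd.DataFrame(
        {
            "district_id": np.arange(1, len(cpr) + 1),
            "state_id": 1,
            "tfr": np.exp(log_tfr),
            "cpr": cpr,
            "total_births_window": births,
        }
    )


class TestOls:
    def test_recovers_noise_free_generating_line(self):
        df = districts_on_line(np.linspace(2.7, 84.8, 50))
        fit = cf.fit_ols(df)
        assert fit.beta0_hat == pytest.approx(1.199, abs=1e-10)
        assert fit.beta1_hat == pytest.approx(-0.0083, abs=1e-10)
        np.testing.assert_allclose(fit.residuals, 0, atol=1e-12)
        assert (fit.robust_weights == 1).all()

    def test_two_points_interpolate_exactly(self):
        df = districts_on_line([10.0, 60.0], beta0=0.9, beta1=-0.004)
        fit = cf.fit_ols(df)
        np.testing.assert_allclose(fit.residuals, 0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_normal_equations_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        df = districts_on_line(rng.uniform(3, 85, 60), noise=rng.normal(0, 0.2, 60))
        fit = cf.fit_ols(df)
        # Independent oracle: solve X'X beta = X'y directly.
        X = np.column_stack([np.ones(60), df["cpr"]])
        y = np.log(df["tfr"])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.beta0_hat == pytest.approx(beta[0], abs=1e-10)
        assert fit.beta1_hat == pytest.approx(beta[1], abs=1e-10)

    def test_degenerate_design_rejected(self):
        df = districts_on_line([50.0, 50.0, 50.0])
        with pytest.raises(EstimationError, match="degenerate"):
            cf.fit_ols(df)

    def test_residual_identity(self, clean_line_districts):
        fit = cf.fit_ols(clean_line_districts)
        manual = np.log(clean_line_districts["tfr"]) - (
            fit.beta0_hat + fit.beta1_hat * clean_line_districts["cpr"]
        )
        np.testing.assert_allclose(fit.residuals, manual, atol=1e-10)


class TestRobust:
    def test_clean_data_equals_ols(self):
        df = districts_on_line(np.linspace(5, 80, 40))
        ols, rob = cf.fit_ols(df), cf.fit_robust(df)
        assert rob.beta0_hat == pytest.approx(ols.beta0_hat, abs=1e-6)
        assert rob.beta1_hat == pytest.approx(ols.beta1_hat, abs=1e-6)
        np.testing.assert_allclose(rob.robust_weights, 1.0)

    def test_gross_outlier_downweighted(self, clean_line_districts):
        base = cf.fit_ols(clean_line_districts)
        spoiled = clean_line_districts.copy()
        spoiled.loc[99, "tfr"] = np.exp(
            1.2 - 0.0083 * spoiled.loc[99, "cpr"] + 2.0
        )
        ols = cf.fit_ols(spoiled)
        rob = cf.fit_robust(spoiled)
        assert rob.converged
        assert rob.robust_weights[99] < 0.05
        assert abs(rob.beta1_hat - base.beta1_hat) / abs(base.beta1_hat) < 0.01
        assert abs(ols.beta1_hat - base.beta1_hat) / abs(base.beta1_hat) > 0.05

    def test_weights_nonincreasing_in_abs_residual(self, clean_line_districts):
        rng = np.random.default_rng(5)
        noisy = clean_line_districts.copy()
        noisy["tfr"] = noisy["tfr"] * np.exp(rng.standard_t(3, len(noisy)) * 0.1)
        fit = cf.fit_robust(noisy)
        order = np.argsort(np.abs(fit.residuals))
        sorted_w = fit.robust_weights[order]
        assert (np.diff(sorted_w) <= 1e-12).all()

    def test_residual_identity(self, clean_line_districts):
        fit = cf.fit_robust(clean_line_districts)
        manual = np.log(clean_line_districts["tfr"]) - (
            fit.beta0_hat + fit.beta1_hat * clean_line_districts["cpr"]
        )
        np.testing.assert_allclose(fit.residuals, manual, atol=1e-10)

    def test_against_statsmodels_rlm(self, clean_line_districts):
        # Independent oracle: a bisquare M-estimator from statsmodels should
        # land close to our Huber-then-bisquare IRLS on mildly noisy data.
        sm = pytest.importorskip("statsmodels.api")
        df = clean_line_districts
        fit = cf.fit_robust(df)
        X = sm.add_constant(df["cpr"].to_numpy())
        rlm = sm.RLM(
            np.log(df["tfr"].to_numpy()), X, M=sm.robust.norms.TukeyBiweight()
        ).fit()
        assert fit.beta0_hat == pytest.approx(rlm.params[0], abs=5e-3)
        assert fit.beta1_hat == pytest.approx(rlm.params[1], rel=0.02)


class TestClassifyGroup:
    @pytest.mark.parametrize(
        "tfr,cpr,expected",
        [(2.0, 40, 1), (3.0, 40, 2), (2.0, 60, 3), (3.0, 60, 4), (2.2, 50, 3)],
    )
    def test_quadrants_and_tie_rule(self, tfr, cpr, expected):
        assert cf.classify_group(tfr, cpr) == expected

    @settings(max_examples=200, derandomize=True)
    @given(
        tfr=st.floats(0.1, 8.0, allow_nan=False),
        cpr=st.floats(0.0, 100.0, allow_nan=False),
    )
    def test_every_point_in_exactly_one_group(self, tfr, cpr):
        assert cf.classify_group(tfr, cpr) in {1, 2, 3, 4}


class TestCounterfactualQuantities:
    def fit_with_slope(self, c):
        return cf.RegressionFit(
            beta0_hat=1.2,
            beta1_hat=-c,
            residuals=np.zeros(1),
            robust_weights=np.ones(1),
            kind="irls",
            n_obs=1,
        )

    def test_zero_cpr_leaves_tfr_unchanged(self):
        fit = self.fit_with_slope(0.0087)
        assert cf.potential_tfr(2.5, 0.0, fit) == pytest.approx(2.5)

    def test_printed_pair_consistency(self):
        # A district at TFR 1.42 with full contraceptive coverage and
        # correction slope 0.0087 would see ~3.39 births per woman.
        fit = self.fit_with_slope(0.0087)
        assert cf.potential_tfr(1.42, 100.0, fit) == pytest.approx(3.39, abs=0.005)

    def test_two_potential_tfr_formulas_agree(self, clean_line_districts):
        fit = cf.fit_robust(clean_line_districts)
        tfr = clean_line_districts["tfr"].to_numpy()
        cpr = clean_line_districts["cpr"].to_numpy()
        via_slope = cf.potential_tfr(tfr, cpr, fit)
        via_residual = np.exp(fit.beta0_hat + fit.residuals)
        np.testing.assert_allclose(via_slope, via_residual, rtol=1e-12)

    def test_ba_and_pib_formulas(self):
        assert cf.births_averted(2.0, 2.0, 500.0) == pytest.approx(0.0)
        assert cf.pib(2.0, 2.0) == pytest.approx(0.0)
        assert cf.births_averted(2.0, 2.5, 1000.0) == pytest.approx(250.0)
        assert cf.pib(2.0, 2.5) == pytest.approx(25.0)
        # Linearity in total births.
        assert cf.births_averted(2.0, 2.5, 3000.0) == pytest.approx(3 * 250.0)

    def test_pib_closed_form_identity(self, clean_line_districts):
        res, fit = cf.run_method2(clean_line_districts)
        c = fit.correction_slope
        closed = 100.0 * (np.exp(c * clean_line_districts["cpr"].to_numpy()) - 1.0)
        merged = res.merge(clean_line_districts, on="district_id")
        np.testing.assert_allclose(merged["pib"], closed, rtol=1e-10)

    def test_nonnegative_when_slope_negative(self, clean_line_districts):
        res, fit = cf.run_method2(clean_line_districts)
        assert fit.beta1_hat < 0
        assert (res["pib"] >= 0).all()
        assert (res["ba"] >= 0).all()
        assert (res["tfrp"] >= res.merge(clean_line_districts, on="district_id")["tfr"] - 1e-12).all()


def heterogeneous_group_districts(n_per_group=40, seed=9):
    """Four quadrants with their own log-linear laws, weak in group 1."""
    rng = np.random.default_rng(seed)
    frames = []
    specs = [
        (1, 0.601, -0.00025, (5, 45)),
        (2, 1.305, -0.0069, (5, 45)),
        (3, 0.735, -0.0026, (52, 80)),
        (4, 1.314, -0.0063, (52, 72)),
    ]
    for g, b0, b1, (lo, hi) in specs:
        cpr = rng.uniform(lo, hi, n_per_group)
        noise = rng.normal(0, 0.01, n_per_group)
        df = districts_on_line(cpr, beta0=b0, beta1=b1, noise=noise)
        df["district_id"] = df["district_id"] + 1000 * g
        frames.append(df)
    return pd.concat(frames, ignore_index=True), specs


class TestMethods:
    def test_method1_recovers_groupwise_slopes(self):
        df, specs = heterogeneous_group_districts()
        res, fits = cf.run_method1(df)
        assert sorted(fits) == [1, 2, 3, 4]
        for g, b0, b1, _ in specs:
            assert fits[g].beta1_hat == pytest.approx(b1, abs=1e-3)

    def test_method1_partition_covers_every_district(self):
        df, _ = heterogeneous_group_districts()
        res, _ = cf.run_method1(df)
        assert len(res) == len(df)
        assert set(res["district_id"]) == set(df["district_id"])

    def test_method1_undersized_group_errors(self):
        df = districts_on_line(np.linspace(5, 45, 10), beta0=1.3, beta1=-0.0069)
        # All in group 2 except one lone low-TFR district.
        df.loc[0, "tfr"] = 1.5
        with pytest.raises(EstimationError, match="group 1"):
            cf.run_method1(df)

    def test_thresholds_outside_range_collapse_to_method2(self, clean_line_districts):
        res1, fits = cf.run_method1(
            clean_line_districts, tfr_threshold=1e9, cpr_threshold=-1.0
        )
        res2, fit2 = cf.run_method2(clean_line_districts)
        assert list(fits) == [3]  # everything low-TFR, high-CPR
        np.testing.assert_allclose(res1["tfrp"], res2["tfrp"], rtol=1e-12)
        np.testing.assert_allclose(res1["pib"], res2["pib"], rtol=1e-12)

    def test_pooled_fit_overstates_low_low_group(self):
        # With group-heterogeneous slopes, the pooled correction slope far
        # exceeds the weak group-1 slope, so Method 2 PIB > Method 1 PIB
        # for low-TFR/low-CPR districts.
        df, _ = heterogeneous_group_districts()
        res1, _ = cf.run_method1(df)
        res2, _ = cf.run_method2(df)
        merged = res1.merge(res2, on="district_id", suffixes=("_m1", "_m2"))
        g1 = merged[merged["group_m1"] == 1]
        assert len(g1) > 0
        assert (g1["pib_m2"] > g1["pib_m1"]).all()
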