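import math

import numpy as np
import pandas as pd
import pytest

import aqindex as aq
from aqindex.glm import (
    ModelSpec,
    QuasiPoissonRegressor,
    adjusted_r2_observed_fitted,
    build_design,
    fit_quasipoisson,
    moving_average_exposure,
    select_df_aic,
)


class TestMovingAverage:
    def test_four_day_window(self):
        out = moving_average_exposure(pd.Series([1.0, 2.0, 3.0, 4.0]), 0, 3)
        assert out.iloc[:3].isna().all()
        assert out.iloc[3] == pytest.approx(2.5)

    def test_zero_lag_is_identity(self):
        s = pd.Series([5.0, 1.0, 7.0])
        assert moving_average_exposure(s, 0, 0).tolist() == s.tolist()

    def test_pure_shift(self):
        out = moving_average_exposure(pd.Series([1.0, 2.0, 3.0, 4.0]), 2, 2)
        assert out.iloc[2:].tolist() == [1.0, 2.0]

    def test_missing_inputs_propagate(self):
        out = moving_average_exposure(pd.Series([1.0, np.nan, 3.0, 4.0, 5.0, 6.0]), 0, 3)
        assert out.iloc[3:5].isna().all()  # windows touching the gap
        assert out.iloc[5] == pytest.approx(4.5)


class TestQuasiPoissonFit:
    def test_intercept_only_is_log_mean(self):
        X = pd.DataFrame({"const": np.ones(3)})
        res = fit_quasipoisson(X, np.array([2, 4, 6]))
        assert res.params["const"] == pytest.approx(math.log(4), rel=1e-9)

    def test_quasi_se_is_poisson_se_times_sqrt_phi(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"const": np.ones(300), "x": rng.standard_normal(300)})
        mu = np.exp(1.0 + 0.3 * X["x"])
        y = rng.negative_binomial(mu / 0.5, 1 / 1.5)  # phi = 1.5
        res = fit_quasipoisson(X, y)
        import statsmodels.api as sm

        poisson = sm.GLM(y, X.to_numpy(), family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(
            res.bse.to_numpy(), poisson.bse * math.sqrt(res.dispersion), rtol=1e-7
        )

    def test_dispersion_near_one_for_poisson_data(self):
        rng = np.random.default_rng(1)
        n = 4000
        X = pd.DataFrame({"const": np.ones(n), "x": rng.standard_normal(n)})
        y = rng.poisson(np.exp(1.5 + 0.2 * X["x"]))
        res = fit_quasipoisson(X, y)
        assert abs(res.dispersion - 1.0) < 3 * math.sqrt(2.0 / n)

    def test_irls_matches_generic_ml_optimizer(self):
        """Twenty random small designs: IRLS vs scipy BFGS on the Poisson
        log-likelihood agree to 1e-6 relative error."""
        from scipy.optimize import minimize
        from scipy.special import gammaln

        rng = np.random.default_rng(7)
        for rep in range(20):
            n, p = 200, int(rng.integers(3, 11))
            X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
            beta_true = rng.normal(0, 0.2, size=p)
            beta_true[0] = 1.0
            y = rng.poisson(np.exp(X @ beta_true))

            def nll(b):
                eta = X @ b
                return -(np.sum(y * eta - np.exp(eta) - gammaln(y + 1)))

            def grad(b):
                return -(X.T @ (y - np.exp(X @ b)))

            def hess(b):
                return (X * np.exp(X @ b)[:, None]).T @ X

            opt = minimize(nll, np.zeros(p), jac=grad, hess=hess,
                           method="Newton-CG", options={"xtol": 1e-12, "maxiter": 500})
            res = fit_quasipoisson(pd.DataFrame(X), y)
            rel = np.abs(res.params.to_numpy() - opt.x) / np.maximum(np.abs(opt.x), 1e-3)
            assert np.max(rel) < 1e-6, f"replicate {rep}: {np.max(rel)}"

    def test_rank_deficiency_names_collinear_columns(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        X = pd.DataFrame({"const": np.ones(100), "x": x, "x_copy": x})
        with pytest.raises(ValueError, match="rank deficient"):
            fit_quasipoisson(X, rng.poisson(np.exp(1 + 0.1 * x)))

    def test_negative_counts_rejected(self):
        X = pd.DataFrame({"const": np.ones(3)})
        with pytest.raises(ValueError, match="non-negative"):
            fit_quasipoisson(X, np.array([1, -2, 3]))

    def test_sklearn_estimator_protocol(self):
        est = QuasiPoissonRegressor(tol=1e-8)
        assert est.get_params() == {"tol": 1e-8, "max_iter": 100}
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        y = rng.poisson(np.exp(1 + 0.2 * X[:, 1]))
        est.fit(X, y)
        assert est.coef_.shape == (2,)
        assert np.allclose(est.predict(X), np.exp(X @ est.coef_))


class TestBuildDesign:
    def test_trend_columns_follow_df_per_season_year(self, sim_series):
        spec = ModelSpec(exposure="pm25", season="cool", temp_df=3, lagtemp_df=3, rh_df=3)
        X, y, _ = build_design(sim_series, spec)
        # 2012-2014 daily: cool blocks 2011(Jan-Feb 2012), 2012, 2013, 2014(Nov-Dec)
        n_sy = 4
        trend_cols = [c for c in X.columns if c.startswith("trend_")]
        assert len(trend_cols) == 8 * n_sy

    def test_dow_indicator_coding_has_six_columns(self, sim_series, fixed_spec):
        X, _, _ = build_design(sim_series, fixed_spec)
        dow_cols = [c for c in X.columns if c.startswith("dow_")]
        assert len(dow_cols) == 6
        assert "dow_Mon" not in X.columns  # Monday is the reference

    def test_rows_dropped_equal_lag_max_on_gap_free_series(self, sim_series):
        spec = ModelSpec(exposure="pm25", season="all", temp_df=3, lagtemp_df=3, rh_df=3)
        X, y, n_dropped = build_design(sim_series, spec)
        assert n_dropped == 3
        assert len(y) == len(sim_series) - 3

    def test_null_design_is_full_design_minus_exposure(self, sim_series, fixed_spec):
        X, _, _ = build_design(sim_series, fixed_spec)
        assert "exposure" in X.columns and "const" in X.columns

    def test_index_exposure_requires_values(self, sim_series):
        spec = ModelSpec(exposure="aqi", season="cool", temp_df=3, lagtemp_df=3, rh_df=3)
        with pytest.raises(ValueError, match="index_values"):
            build_design(sim_series, spec)


class TestAicSelection:
    def test_single_candidate_grid_returns_it(self, sim_series):
        spec = ModelSpec(exposure="pm25", season="cool", temp_df="aic",
                         lagtemp_df=3, rh_df=3, aic_grid=(4,))
        out = select_df_aic(sim_series, spec)
        assert out.temp_df == 4

    def test_aic_equals_definition_from_fitted_means(self, sim_series, fixed_spec):
        from scipy.special import gammaln

        X, y, nd = build_design(sim_series, fixed_spec)
        res = fit_quasipoisson(X, y, n_dropped=nd)
        mu = res.fitted_values.to_numpy()
        yv = y.to_numpy()
        ll = np.sum(yv * np.log(mu) - mu - gammaln(yv + 1))
        assert res.quasi_aic == pytest.approx(2 * len(res.params) - 2 * ll, rel=1e-10)

    def test_linear_temperature_effect_selects_smallest_df(self):
        """Counts generated with a purely linear temperature effect: AIC
        should pick the smallest candidate df in most replicates."""
        rng = np.random.default_rng(99)
        wins = 0
        reps = 30
        for rep in range(reps):
            n = 400
            dates = pd.date_range("2013-01-01", periods=n)
            temp = 60 + 10 * np.sin(np.arange(n) / 30) + rng.normal(0, 3, n)
            mu = np.exp(3.0 + 0.01 * (temp - 60))
            frame = pd.DataFrame({
                "date": dates, "pm25": rng.uniform(5, 20, n), "o3": rng.uniform(20, 60, n),
                "no2": rng.uniform(5, 30, n), "temp": temp, "rh": rng.uniform(30, 80, n),
                "count": rng.poisson(mu),
            })
            series = aq.DailySeries(f"c{rep}", frame)
            spec = ModelSpec(exposure="pm25", season="all", trend_df_per_season_year=4,
                             temp_df="aic", lagtemp_df=2, rh_df=2, aic_grid=(2, 3, 4, 5))
            out = select_df_aic(series, spec)
            wins += out.temp_df == 2
        assert wins > reps / 2


class TestAdjustedR2:
    def test_perfect_fit_is_one(self):
        y = np.arange(20.0)
        assert adjusted_r2_observed_fitted(y, y, 2) == pytest.approx(1.0)

    def test_uncorrelated_fit_near_zero(self):
        rng = np.random.default_rng(4)
        y, f = rng.poisson(10, 5000).astype(float), rng.normal(10, 1, 5000)
        assert abs(adjusted_r2_observed_fitted(y, f, 2)) < 0.05

    def test_invariant_to_affine_transform_of_fitted(self):
        rng = np.random.default_rng(5)
        y = rng.poisson(10, 200).astype(float)
        f = y + rng.normal(0, 2, 200)
        a = adjusted_r2_observed_fitted(y, f, 3)
        b = adjusted_r2_observed_fitted(y, 5.0 - 2.0 * f, 3)
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_variance_fitted_is_missing(self):
        assert math.isnan(adjusted_r2_observed_fitted(np.arange(10.0), np.ones(10), 2))


def test_parameter_recovery_covers_truth(sim_series):
    """Full-model fit on a simulated county recovers the injected exposure
    coefficient within its 95% CI (single-replicate sanity check; the
    calibration study lives in the acceptance suite)."""
    spec = ModelSpec(exposure="pm25", season="all", temp_df=3, lagtemp_df=3, rh_df=3)
    est = aq.estimate_association(sim_series, spec)
    truth = sim_series.true_beta_per_unit["pm25"] * est.iqr_used
    z = aq.association.Z_95
    assert est.log_rr - z * est.se_log_rr <= truth <= est.log_rr + z * est.se_log_rr
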