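"""DLM filter/smoother, OLS sensitivity, trend estimation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.diagnostic import acorr_ljungbox

import precsens as ps
from precsens.errors import (
    CollinearityError,
    InsufficientDataError,
    InvalidSpecError,
    NormalizationError,
)


def _bundle_frame(series):
    bundle = ps.make_anomaly_bundle(series, standardize=True)
    df = bundle.frame(multivariate=True)
    y = df.pop("ndvi")
    return df, y


class TestDLMOracle:
    def test_zero_anomalies_zero_prior_stay_zero(self):
        idx = pd.date_range("1981-01", periods=60, freq="MS")
        X = pd.DataFrame({"x": np.linspace(-1, 1, 60)}, index=idx)
        y = pd.Series(np.zeros(60), index=idx)
        model = ps.DynamicLinearRegression(
            trend_order=0, n_harmonics=0, standardize=False,
            learn_obs_variance=False, obs_variance=1.0,
        ).fit(X, y)
        np.testing.assert_allclose(model.coef_trajectory_.to_numpy(), 0.0, atol=1e-12)

    def test_unit_discounts_equal_batch_ols(self, ramp_bundle):
        """With delta = 1, no trend/seasonal and a diffuse prior, the filter
        is batch least squares; the smoothed trajectory is flat at that
        solution."""
        series, _ = ramp_bundle
        df, y = _bundle_frame(series)
        model = ps.DynamicLinearRegression(
            trend_order=0, n_harmonics=0,
            discount_trend=1.0, discount_seasonal=1.0, discount_regression=1.0,
            prior_coef_scale=1e8, standardize=False, smooth=True,
        ).fit(df, y)
        ok = y.notna() & df.notna().all(axis=1)
        ols = sm.OLS(y[ok], df[ok]).fit()
        final = model.coef_trajectory_filtered_.iloc[-1]
        np.testing.assert_allclose(final, ols.params, rtol=1e-6)
        smoothed = model.coef_trajectory_.iloc[5]
        np.testing.assert_allclose(smoothed, ols.params, rtol=1e-4)

    def test_posterior_variance_nonincreasing_with_unit_discounts(self):
        idx = pd.date_range("1981-01", periods=120, freq="MS")
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"x": rng.standard_normal(120)}, index=idx)
        y = pd.Series(0.5 * X["x"].to_numpy() + 0.1 * rng.standard_normal(120), index=idx)
        model = ps.DynamicLinearRegression(
            trend_order=0, n_harmonics=0,
            discount_regression=1.0, discount_trend=1.0, discount_seasonal=1.0,
            learn_obs_variance=False, obs_variance=0.01,
            standardize=False, smooth=False,
        ).fit(X, y)
        var = model.coef_variance_["x"].to_numpy()
        assert np.all(np.diff(var) <= 1e-12)

    def test_missing_observations_propagate_state(self, ramp_bundle):
        series, _ = ramp_bundle
        series = series.copy()
        series.iloc[200:205, series.columns.get_loc("ndvi")] = np.nan
        df, y = _bundle_frame(series)
        model = ps.dlm_fit(
            ps.make_anomaly_bundle(series, standardize=True)
        )
        theta = model.theta("prec")
        assert theta.notna().all()


class TestDLMRecovery:
    def test_ramp_recovery_rmse_and_slope(self, ramp_bundle):
        series, truth = ramp_bundle
        bundle = ps.make_anomaly_bundle(series, standardize=True)
        model = ps.dlm_fit(bundle)
        theta = model.theta("prec").to_numpy()
        rmse = float(np.sqrt(np.nanmean((theta - truth["theta_prec"].to_numpy()) ** 2)))
        assert rmse < 0.08
        slope = np.polyfit(np.arange(len(theta)) / 12.0, theta, 1)[0]
        assert slope > 0

    def test_tracks_piecewise_shift_within_24_months(self):
        clim = ps.make_climate_series(ps.ClimateSpec(n_months=420, seed=41))
        spec0 = ps.SensitivitySpec(
            theta_prec=("piecewise", [(0, 0.2), (209, 0.2), (210, 0.6), (419, 0.6)]),
            theta_ndvi=0.3, noise_sd=1.0, seed=42,
        )
        nsd = ps.synth.signal_noise_sd(clim, spec0, snr=2.0)
        series, truth = ps.make_ndvi_series(
            clim, dataclasses.replace(spec0, noise_sd=nsd)
        )
        bundle = ps.make_anomaly_bundle(series, standardize=True)
        model = ps.dlm_fit(bundle, discount_regression=0.95)
        theta = model.theta("prec").to_numpy()
        after = slice(210 + 24, 420)
        err = np.abs(theta[after] - truth["theta_prec"].to_numpy()[after])
        assert np.nanmean(err) < 0.1
        # the trajectory has settled on the post-shift level
        assert abs(np.nanmean(theta[after]) - 0.6) < 0.1

    def test_forecast_residuals_serially_uncorrelated(self):
        """One-step innovations on well-specified generator data pass a
        Ljung-Box whiteness check (median p over seeds)."""
        pvals = []
        for seed in range(10):
            clim = ps.make_climate_series(ps.ClimateSpec(n_months=360, seed=100 + seed))
            spec0 = ps.SensitivitySpec(theta_prec=0.4, theta_ndvi=0.3,
                                       noise_sd=1.0, seed=200 + seed)
            nsd = ps.synth.signal_noise_sd(clim, spec0, snr=2.0)
            series, _ = ps.make_ndvi_series(
                clim, dataclasses.replace(spec0, noise_sd=nsd)
            )
            model = ps.dlm_fit(ps.make_anomaly_bundle(series, standardize=True))
            resid = model.forecast_residuals_.dropna().to_numpy()[24:]
            lb = acorr_ljungbox(resid, lags=[12])
            pvals.append(float(lb["lb_pvalue"].iloc[0]))
        assert np.median(pvals) > 0.01

    def test_univariate_multivariate_agreement_without_confounders(self, small_transect):
        ds = small_transect
        uni, multi = [], []
        for j in range(ds.sizes["pixel"]):
            series = pd.DataFrame(
                {v: ds[v].isel(pixel=j).values for v in ("ndvi", "prec", "temp", "cloud")},
                index=ds.indexes["time"],
            )
            bundle = ps.make_anomaly_bundle(series, standardize=True)
            uni.append(ps.dlm_fit(bundle, variant="univariate").theta("prec").mean())
            multi.append(ps.dlm_fit(bundle, variant="multivariate").theta("prec").mean())
        assert np.corrcoef(uni, multi)[0, 1] > 0.9

    def test_nonpositive_discount_rejected(self, ramp_bundle):
        series, _ = ramp_bundle
        bundle = ps.make_anomaly_bundle(series)
        with pytest.raises(InvalidSpecError):
            ps.dlm_fit(bundle, discount_regression=0.0)


class TestStaticSensitivity:
    def test_noiseless_exact_identification(self, noiseless_bundle):
        series, _ = noiseless_bundle
        fit = ps.ols_sensitivity(
            series, variant="multivariate", standardize=True, windows=("m-1",)
        )
        assert fit.theta_prec_ == pytest.approx(0.3, abs=2e-3)
        assert fit.coef_["ndvi_lag1"] == pytest.approx(0.5, abs=2e-3)

    def test_zero_variance_precip_raises_collinearity(self):
        idx = pd.date_range("1981-01", periods=120, freq="MS")
        rng = np.random.default_rng(7)
        series = pd.DataFrame(
            {
                "ndvi": rng.standard_normal(120),
                "prec": np.full(120, 50.0),
                "temp": 10 + rng.standard_normal(120),
                "cloud": 0.5 + 0.01 * rng.standard_normal(120),
            },
            index=idx,
        )
        with pytest.raises(CollinearityError):
            ps.ols_sensitivity(series, windows=("m-1",))

    def test_window_selection_recovers_generating_lag(self):
        """Selection across all six windows picks the generating previous-
        month window in >= 95% of seeded replicates at SNR 2."""
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            clim = ps.make_climate_series(
                ps.ClimateSpec(n_months=420, seed=1000 + i)
            )
            spec0 = ps.SensitivitySpec(
                theta_prec=0.4, theta_ndvi=0.3, noise_sd=1.0, seed=2000 + i
            )
            nsd = ps.synth.signal_noise_sd(clim, spec0, snr=2.0)
            series, _ = ps.make_ndvi_series(
                clim, dataclasses.replace(spec0, noise_sd=nsd)
            )
            fit = ps.ols_sensitivity(series, standardize=True)
            hits += fit.window_ == "m-1"
        assert hits / n_rep >= 0.95

    def test_two_month_driver_selects_matching_window(self):
        """When the true driver is the current-and-previous-month mean,
        selection favours that window."""
        hits = 0
        for i in range(20):
            clim = ps.make_climate_series(ps.ClimateSpec(n_months=420, seed=300 + i))
            spec0 = ps.SensitivitySpec(
                theta_prec=0.4, theta_ndvi=0.3, noise_sd=1.0,
                lag_window="m0:m-1", seed=400 + i,
            )
            nsd = ps.synth.signal_noise_sd(clim, spec0, snr=2.0)
            series, _ = ps.make_ndvi_series(
                clim, dataclasses.replace(spec0, noise_sd=nsd)
            )
            fit = ps.ols_sensitivity(series, standardize=True)
            hits += fit.window_ == "m0:m-1"
        assert hits >= 16

    def test_too_few_months_rejected(self):
        idx = pd.date_range("1981-01", periods=30, freq="MS")
        rng = np.random.default_rng(8)
        series = pd.DataFrame(
            {
                "ndvi": rng.standard_normal(30),
                "prec": 50 + 10 * rng.standard_normal(30),
                "temp": 10 + rng.standard_normal(30),
                "cloud": np.clip(0.5 + 0.1 * rng.standard_normal(30), 0, 1),
            },
            index=idx,
        )
        with pytest.raises(InsufficientDataError):
            ps.ols_sensitivity(series)


class TestTrends:
    def test_constant_trajectory_has_zero_trend(self):
        idx = pd.date_range("1981-01", periods=120, freq="MS")
        res = ps.sensitivity_trend(pd.Series(0.4, index=idx), n_boot=0)
        assert res.normalized_pct_yr == pytest.approx(0.0, abs=1e-10)

    def test_linear_ramp_arithmetic_identity(self):
        # 0.2 -> 0.6 over 35 years, mean 0.4: 100 * (0.4/35) / 0.4
        idx = pd.date_range("1981-01", periods=420, freq="MS")
        traj = pd.Series(np.linspace(0.2, 0.6, 420), index=idx)
        res = ps.sensitivity_trend(traj, n_boot=0)
        expected = 100.0 * (0.4 / (419 / 12.0)) / 0.4
        assert res.normalized_pct_yr == pytest.approx(expected, rel=1e-6)

    def test_zero_mean_rejected(self):
        idx = pd.date_range("1981-01", periods=48, freq="MS")
        traj = pd.Series(np.tile([1.0, -1.0], 24), index=idx)
        with pytest.raises(NormalizationError):
            ps.sensitivity_trend(traj, n_boot=0)

    def test_bootstrap_interval_covers_truth(self):
        """Year-block bootstrap CI covers the generating normalized trend
        in >= 90% of replicates."""
        idx = pd.date_range("1981-01", periods=420, freq="MS")
        true_traj = np.linspace(0.2, 0.6, 420)
        true_trend = 100.0 * ((0.6 - 0.2) / (419 / 12.0)) / 0.4
        rng = np.random.default_rng(9)
        cover = 0
        n_rep = 100
        for i in range(n_rep):
            noisy = true_traj + 0.05 * rng.standard_normal(420)
            res = ps.sensitivity_trend(
                pd.Series(noisy, index=idx), n_boot=300, seed=i
            )
            cover += res.ci_low <= true_trend <= res.ci_high
        assert cover / n_rep >= 0.90

    def test_theil_sen_option(self):
        idx = pd.date_range("1981-01", periods=120, freq="MS")
        traj = pd.Series(np.linspace(0.3, 0.5, 120), index=idx)
        a = ps.sensitivity_trend(traj, n_boot=0, estimator="theil-sen")
        b = ps.sensitivity_trend(traj, n_boot=0, estimator="ols")
        assert a.normalized_pct_yr == pytest.approx(b.normalized_pct_yr, rel=1e-6)


class TestRegionalMedian:
    def test_identical_trends_give_degenerate_interval(self):
        trends = np.full(20, 0.37)
        out = ps.regional_median_trend(trends, n_boot=200)
        row = out.loc["all"]
        assert row["median"] == pytest.approx(0.37)
        assert row["ci_high"] - row["ci_low"] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_distribution_centre_recovered(self):
        rng = np.random.default_rng(12)
        trends = 0.624 + 0.2 * rng.standard_normal(400)
        out = ps.regional_median_trend(trends, n_boot=2000, seed=1)
        row = out.loc["all"]
        assert row["ci_low"] <= 0.624 <= row["ci_high"]

    def test_single_pixel_class_rejected(self):
        trends = np.concatenate([np.full(15, 0.5), [0.1]])
        classes = np.array(["a"] * 15 + ["b"])
        with pytest.raises(InsufficientDataError):
            ps.regional_median_trend(trends, classes)
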