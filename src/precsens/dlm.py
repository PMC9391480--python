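"""Precipitation-sensitivity estimators: static OLS and a discount DLM.

The dynamic linear model is a Gaussian state-space regression

    y_t = F_t' theta_t + nu_t,        nu_t ~ N(0, V_t)
    theta_t = G theta_{t-1} + w_t,

whose state stacks a local polynomial trend, seasonal Fourier harmonics and
a time-varying regression block over the anomaly drivers.  Instead of
specifying the evolution covariance W_t explicitly, each block's prior
covariance is inflated by a per-block discount factor delta in (0, 1]
(W_t is chosen so that R_t = G C_{t-1} G' / delta blockwise), the standard
discount construction.  The observation variance is learned online with a
discounted inverse-gamma recursion.  With all discounts equal to 1, no
trend/seasonal blocks and a diffuse prior, the filter reproduces batch
ordinary least squares exactly; tests hold it to that oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    CollinearityError,
    ConditioningError,
    InsufficientDataError,
    InvalidSpecError,
    NormalizationError,
)
from . import preprocess
from .preprocess import AnomalyBundle, LAG_WINDOWS, make_anomaly_bundle

MIN_OLS_MONTHS = 36


# ---------------------------------------------------------------------------
# dynamic linear model
# ---------------------------------------------------------------------------

class DynamicLinearRegression(BaseEstimator, RegressorMixin):
    """Time-varying linear regression via Kalman filtering with discounts.

    Parameters
    ----------
    trend_order : 0 disables the local trend block, 1 is a local level,
        2 a local linear trend.
    n_harmonics : number of seasonal Fourier harmonics (0 disables).
    period : seasonal period in time steps (12 for monthly data).
    discount_trend, discount_seasonal, discount_regression : per-block
        discount factors in (0, 1]; 1 freezes the block (static
        coefficients), smaller values let it drift faster.
    discount_obs_variance : discount of the inverse-gamma observation
        variance recursion (ignored when ``learn_obs_variance`` is False).
    prior_coef_scale : prior covariance is this scale times the identity
        (on the standardized-regressor scale, in units of the observation
        variance).  Large values give a diffuse prior; note that with
        discounting the early evolution noise is proportional to the prior
        covariance, so the default is weakly informative (coefficients on
        the standardized scale are O(1)) rather than diffuse.
    obs_variance : fixed observation variance, or the initial estimate when
        learning; ``None`` initializes from the sample variance of y.
    standardize : center/scale the regressors internally; coefficients are
        reported back on the raw scale (``coef_trajectory_``) and on the
        standardized scale (``coef_trajectory_std_``).
    smooth : if True, ``coef_trajectory_`` is the fixed-interval smoothed
        (retrospective) trajectory; the filtered one is always available.
    """

    def __init__(
        self,
        trend_order: int = 1,
        n_harmonics: int = 2,
        period: int = 12,
        discount_trend: float = 0.98,
        discount_seasonal: float = 0.99,
        discount_regression: float = 0.995,
        discount_obs_variance: float = 0.99,
        prior_coef_scale: float = 10.0,
        learn_obs_variance: bool = True,
        obs_variance: float | None = None,
        standardize: bool = True,
        smooth: bool = True,
    ):
        self.trend_order = trend_order
        self.n_harmonics = n_harmonics
        self.period = period
        self.discount_trend = discount_trend
        self.discount_seasonal = discount_seasonal
        self.discount_regression = discount_regression
        self.discount_obs_variance = discount_obs_variance
        self.prior_coef_scale = prior_coef_scale
        self.learn_obs_variance = learn_obs_variance
        self.obs_variance = obs_variance
        self.standardize = standardize
        self.smooth = smooth

    # -- construction helpers ------------------------------------------------

    def _validate(self) -> None:
        for name in (
            "discount_trend",
            "discount_seasonal",
            "discount_regression",
            "discount_obs_variance",
        ):
            d = getattr(self, name)
            if not 0 < d <= 1:
                raise InvalidSpecError(f"{name} must lie in (0, 1], got {d}")
        if self.trend_order not in (0, 1, 2):
            raise InvalidSpecError("trend_order must be 0, 1 or 2")
        if self.n_harmonics < 0 or self.period <= 1:
            raise InvalidSpecError("need n_harmonics >= 0 and period > 1")
        if self.prior_coef_scale <= 0:
            raise InvalidSpecError("prior_coef_scale must be > 0")

    def _system(self, p: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (G, F_static, discount vector); regression F entries are
        filled per step with the regressor values."""
        blocks, fs, deltas = [], [], []
        if self.trend_order == 1:
            blocks.append(np.array([[1.0]]))
            fs.extend([1.0])
            deltas.extend([self.discount_trend])
        elif self.trend_order == 2:
            blocks.append(np.array([[1.0, 1.0], [0.0, 1.0]]))
            fs.extend([1.0, 0.0])
            deltas.extend([self.discount_trend] * 2)
        for j in range(1, self.n_harmonics + 1):
            w = 2.0 * np.pi * j / self.period
            blocks.append(
                np.array([[np.cos(w), np.sin(w)], [-np.sin(w), np.cos(w)]])
            )
            fs.extend([1.0, 0.0])
            deltas.extend([self.discount_seasonal] * 2)
        if p:
            blocks.append(np.eye(p))
            fs.extend([0.0] * p)  # placeholders, filled with x_t
            deltas.extend([self.discount_regression] * p)
        q = sum(b.shape[0] for b in blocks)
        G = np.zeros((q, q))
        i = 0
        for b in blocks:
            k = b.shape[0]
            G[i : i + k, i : i + k] = b
            i += k
        return G, np.array(fs), np.array(deltas)

    # -- fitting -------------------------------------------------------------

    def fit(self, X, y):
        """Filter (and optionally smooth) the coefficient trajectory.

        Rows with NaN in X or y are treated as missing observations: the
        state propagates without an update.
        """
        self._validate()
        X_arr, y_arr, index, names = _coerce_xy(X, y)
        n, p = X_arr.shape
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = p

        valid = np.isfinite(y_arr) & np.all(np.isfinite(X_arr), axis=1)
        if valid.sum() < max(p + 2, 8):
            raise InsufficientDataError(
                f"only {int(valid.sum())} complete months for a {p}-regressor DLM"
            )
        if self.standardize:
            mu = X_arr[valid].mean(axis=0)
            sd = X_arr[valid].std(axis=0, ddof=1)
            if np.any(sd == 0):
                bad = [names[j] for j in np.flatnonzero(sd == 0)]
                raise CollinearityError(f"zero-variance regressors: {bad}")
            Xs = (X_arr - mu) / sd
        else:
            mu = np.zeros(p)
            sd = np.ones(p)
            Xs = X_arr
        self._x_mean_, self._x_scale_ = mu, sd

        G, F0, deltas = self._system(p)
        q = len(F0)
        reg_slice = slice(q - p, q) if p else slice(0, 0)
        inv_sqrt_delta = 1.0 / np.sqrt(deltas)

        s = (
            float(self.obs_variance)
            if self.obs_variance is not None
            else float(np.var(y_arr[valid], ddof=1)) or 1.0
        )
        if s <= 0:
            raise InvalidSpecError("obs_variance must be > 0")
        n_dof = 1.0
        d_scale = s * n_dof

        m = np.zeros(q)
        C = self.prior_coef_scale * s * np.eye(q)

        a_hist = np.empty((n, q))
        R_hist = np.empty((n, q, q))
        m_hist = np.empty((n, q))
        C_hist = np.empty((n, q, q))
        s_hist = np.empty(n)
        f_hist = np.full(n, np.nan)
        e_std = np.full(n, np.nan)

        dv = self.discount_obs_variance if self.learn_obs_variance else 1.0
        for t in range(n):
            a = G @ m
            P = G @ C @ G.T
            R = P * np.outer(inv_sqrt_delta, inv_sqrt_delta)
            R = 0.5 * (R + R.T)
            if not valid[t]:
                m, C = a, R
            else:
                F = F0.copy()
                if p:
                    F[reg_slice] = Xs[t]
                f = float(F @ a)
                Qt = float(F @ R @ F) + s
                if not np.isfinite(Qt) or Qt <= 0:
                    raise ConditioningError(
                        f"non-positive forecast variance at month index {t}"
                    )
                e = y_arr[t] - f
                A = (R @ F) / Qt
                if self.learn_obs_variance:
                    n_dof = dv * n_dof + 1.0
                    d_scale = dv * d_scale + s * e * e / Qt
                    s_new = d_scale / n_dof
                else:
                    s_new = s
                m = a + A * e
                C = (s_new / s) * (R - np.outer(A, A) * Qt)
                C = 0.5 * (C + C.T)
                f_hist[t] = f
                e_std[t] = e / np.sqrt(Qt)
                s = s_new
            a_hist[t], R_hist[t] = a, R
            m_hist[t], C_hist[t] = m, C
            s_hist[t] = s

        # rescale historical covariances to the final variance estimate
        if self.learn_obs_variance:
            scale = s_hist[-1] / s_hist
            C_hist *= scale[:, None, None]
            R_hist *= np.concatenate([[s_hist[-1] / s_hist[0]], scale[:-1]])[
                :, None, None
            ]

        sm_m, sm_C = m_hist.copy(), C_hist.copy()
        if self.smooth:
            for t in range(n - 2, -1, -1):
                Rn = R_hist[t + 1]
                try:
                    B = np.linalg.solve(Rn.T, (C_hist[t] @ G.T).T).T
                except np.linalg.LinAlgError as exc:  # pragma: no cover
                    raise ConditioningError(
                        f"singular one-step covariance at month index {t + 1}"
                    ) from exc
                sm_m[t] = m_hist[t] + B @ (sm_m[t + 1] - a_hist[t + 1])
                SC = C_hist[t] + B @ (sm_C[t + 1] - Rn) @ B.T
                sm_C[t] = 0.5 * (SC + SC.T)

        traj_m = sm_m if self.smooth else m_hist
        traj_C = sm_C if self.smooth else C_hist

        coef_std = traj_m[:, reg_slice]
        var_std = np.stack([np.diag(c)[reg_slice] for c in traj_C])
        self.coef_trajectory_std_ = pd.DataFrame(coef_std, index=index, columns=names)
        self.coef_variance_std_ = pd.DataFrame(var_std, index=index, columns=names)
        self.coef_trajectory_ = self.coef_trajectory_std_ / sd
        self.coef_variance_ = self.coef_variance_std_ / sd**2
        filt = m_hist[:, reg_slice]
        self.coef_trajectory_filtered_ = pd.DataFrame(
            filt / sd, index=index, columns=names
        )
        self.coef_trajectory_filtered_std_ = pd.DataFrame(
            filt, index=index, columns=names
        )
        self.level_trajectory_ = pd.Series(
            traj_m[:, 0] if self.trend_order else np.zeros(n), index=index
        )
        self.forecast_residuals_ = pd.Series(e_std, index=index)
        self.forecast_ = pd.Series(f_hist, index=index)
        self.observation_variance_ = float(s_hist[-1])
        self.observation_variance_path_ = pd.Series(s_hist, index=index)
        self.smoothed_ = bool(self.smooth)
        self._final_state = traj_m[-1]
        self._G = G
        return self

    def predict(self, X):
        """Linear prediction with the final-state regression coefficients."""
        X_arr, _, index, _ = _coerce_xy(X, None)
        Xs = (X_arr - self._x_mean_) / self._x_scale_
        p = self.n_features_in_
        coef = self._final_state[-p:] if p else np.zeros(0)
        level = self._final_state[0] if self.trend_order else 0.0
        return pd.Series(Xs @ coef + level, index=index)

    def theta(self, name: str = "prec", std: bool = False) -> pd.Series:
        """Coefficient trajectory of one named regressor."""
        traj = self.coef_trajectory_std_ if std else self.coef_trajectory_
        if name not in traj.columns:
            raise KeyError(f"no regressor named {name!r}; have {list(traj.columns)}")
        return traj[name]


def _coerce_xy(X, y):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        index = X.index
        X_arr = X.to_numpy(dtype=float)
    else:
        X_arr = np.asarray(X, dtype=float)
        if X_arr.ndim == 1:
            X_arr = X_arr[:, None]
        names = [f"x{j}" for j in range(X_arr.shape[1])]
        index = pd.RangeIndex(len(X_arr))
    if y is None:
        return X_arr, None, index, names
    y_arr = np.asarray(y, dtype=float).ravel()
    if len(y_arr) != len(X_arr):
        raise InvalidSpecError("X and y lengths differ")
    return X_arr, y_arr, index, names


def dlm_fit(
    bundle: AnomalyBundle,
    variant: str = "multivariate",
    **dlm_params,
) -> DynamicLinearRegression:
    """Fit the DLM to an anomaly bundle; returns the fitted estimator.

    The regression block covers the lag-window precipitation anomaly, the
    lag-1 greenness anomaly and (for the multivariate variant) the
    current-month temperature and cloud anomalies.
    """
    df = bundle.frame(multivariate=(variant == "multivariate"))
    y = df.pop("ndvi")
    model = DynamicLinearRegression(**dlm_params)
    return model.fit(df, y)


# ---------------------------------------------------------------------------
# static (OLS) sensitivity with lag-window selection
# ---------------------------------------------------------------------------

class StaticSensitivity(BaseEstimator):
    """Multivariate (or univariate) OLS sensitivity with lag selection.

    For each candidate precipitation lag window an ordinary-least-squares
    regression of the greenness anomaly on the windowed precipitation
    anomaly, (optionally) temperature and cloud anomalies, and the lag-1
    greenness anomaly is fitted; the window maximizing the model-selection
    score (coefficient of determination by default, AIC optionally) is
    selected and its precipitation coefficient reported.

    ``fit`` accepts the raw monthly series DataFrame (columns ``ndvi``,
    ``prec`` and optionally ``temp``/``cloud``) because lag aggregation is
    part of the model-selection loop.
    """

    def __init__(
        self,
        variant: str = "multivariate",
        windows: tuple[str, ...] | None = None,
        score: str = "r2",
        standardize: bool = False,
        mask_cold: bool = True,
    ):
        self.variant = variant
        self.windows = windows
        self.score = score
        self.standardize = standardize
        self.mask_cold = mask_cold

    def fit(self, series: pd.DataFrame, y=None):
        if self.variant not in ("univariate", "multivariate"):
            raise InvalidSpecError("variant must be univariate or multivariate")
        if self.score not in ("r2", "aic"):
            raise InvalidSpecError("score must be 'r2' or 'aic'")
        windows = tuple(self.windows) if self.windows else tuple(LAG_WINDOWS)
        for w in windows:
            if w not in LAG_WINDOWS:
                raise InvalidSpecError(f"unknown lag window {w!r}")

        results = {}
        for w in windows:
            bundle = make_anomaly_bundle(
                series,
                lag_window=w,
                mask_cold=self.mask_cold,
                standardize=self.standardize,
            )
            df = bundle.frame(multivariate=(self.variant == "multivariate"))
            df = df.dropna()
            if len(df) < MIN_OLS_MONTHS:
                raise InsufficientDataError(
                    f"window {w}: only {len(df)} complete months (need "
                    f">= {MIN_OLS_MONTHS})"
                )
            y_v = df.pop("ndvi")
            X = sm.add_constant(df)
            sv = np.linalg.svd(X.to_numpy(), compute_uv=False)
            if sv[-1] < 1e-10 * sv[0]:
                raise CollinearityError(
                    f"singular design matrix for lag window {w}"
                )
            fit = sm.OLS(y_v, X).fit()
            results[w] = {
                "coef": fit.params.drop("const"),
                "bse": fit.bse.drop("const"),
                "r2": float(fit.rsquared),
                "aic": float(fit.aic),
                "nobs": int(fit.nobs),
            }
        if self.score == "r2":
            best = max(results, key=lambda w: results[w]["r2"])
        else:
            best = min(results, key=lambda w: results[w]["aic"])
        self.window_ = best
        self.coef_ = results[best]["coef"]
        self.bse_ = results[best]["bse"]
        self.theta_prec_ = float(self.coef_["prec"])
        self.results_ = results
        return self


def ols_sensitivity(
    series: pd.DataFrame,
    variant: str = "multivariate",
    windows: tuple[str, ...] | None = None,
    **kwargs,
) -> StaticSensitivity:
    """Fit :class:`StaticSensitivity`; returns the fitted estimator."""
    return StaticSensitivity(variant=variant, windows=windows, **kwargs).fit(series)


# ---------------------------------------------------------------------------
# trends
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendResult:
    """Normalized trend of a coefficient trajectory."""

    slope_per_yr: float
    mean: float
    normalized_pct_yr: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_boot: int = 0


def sensitivity_trend(
    trajectory: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    estimator: str = "ols",
) -> TrendResult:
    """Normalized trend (% per year) of a monthly coefficient trajectory.

    The linear slope over time (per year) is divided by the record-mean
    coefficient and multiplied by 100.  The confidence interval comes from a
    block bootstrap that resamples whole years of fit residuals, preserving
    within-year dependence.
    """
    traj = pd.Series(trajectory).dropna()
    if len(traj) < 2:
        raise InsufficientDataError("need >= 2 valid points for a trend")
    mean = float(traj.mean())
    sd = float(traj.std(ddof=1)) if len(traj) > 2 else abs(mean)
    if abs(mean) < 1e-10 * max(1.0, sd):
        raise NormalizationError("record-mean coefficient is ~ 0; cannot normalize")

    t_yr = _years_axis(traj.index)
    vals = traj.to_numpy(dtype=float)
    slope, intercept = _slope(t_yr, vals, estimator)
    normalized = 100.0 * slope / mean

    ci_low = ci_high = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        fitted = intercept + slope * t_yr
        resid = vals - fitted
        blocks = _year_blocks(traj.index, len(traj))
        boots = np.empty(n_boot)
        for b in range(n_boot):
            picks = rng.integers(0, len(blocks), len(blocks))
            r = np.concatenate([resid[blocks[i]] for i in picks])[: len(vals)]
            if len(r) < len(vals):
                r = np.pad(r, (0, len(vals) - len(r)), mode="wrap")
            yb = fitted + r
            sb, _ = _slope(t_yr, yb, estimator)
            boots[b] = 100.0 * sb / np.mean(yb)
        ci_low, ci_high = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return TrendResult(slope, mean, normalized, float(ci_low), float(ci_high), n_boot)


def _years_axis(index) -> np.ndarray:
    if isinstance(index, pd.DatetimeIndex):
        t = (index.year - index.year[0]) * 12 + (index.month - index.month[0])
        return t.to_numpy(dtype=float) / 12.0
    return np.asarray(index, dtype=float) / 12.0


def _slope(t, y, estimator):
    if estimator == "theil-sen":
        res = stats.theilslopes(y, t)
        return float(res.slope), float(res.intercept)
    if estimator != "ols":
        raise InvalidSpecError("estimator must be 'ols' or 'theil-sen'")
    coef = np.polyfit(t, y, 1)
    return float(coef[0]), float(coef[1])


def _year_blocks(index, n) -> list[np.ndarray]:
    if isinstance(index, pd.DatetimeIndex):
        years = index.year.to_numpy()
    else:
        years = np.asarray(index) // 12
    return [np.flatnonzero(years == y) for y in np.unique(years)]


def regional_median_trend(
    trends,
    classes=None,
    n_boot: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    min_pixels: int = 10,
) -> pd.DataFrame:
    """Median per-pixel trend per region class, with a percentile bootstrap CI.

    The bootstrap resamples pixels within each class (n_boot resamples,
    default 5000) and reports the (alpha/2, 1-alpha/2) quantiles of the
    resampled medians.
    """
    trends = np.asarray(trends, dtype=float)
    if classes is None:
        classes = np.full(trends.shape, "all")
    classes = np.asarray(classes)
    if classes.shape != trends.shape:
        raise InvalidSpecError("trends and classes must have the same shape")
    rng = np.random.default_rng(seed)
    rows = []
    for cls in pd.unique(classes):
        x = trends[(classes == cls) & np.isfinite(trends)]
        if len(x) == 0:
            raise InsufficientDataError(f"class {cls!r} is empty")
        if len(x) < min_pixels:
            raise InsufficientDataError(
                f"class {cls!r} has {len(x)} pixels; need >= {min_pixels}"
            )
        med = float(np.median(x))
        idx = rng.integers(0, len(x), size=(n_boot, len(x)))
        meds = np.median(x[idx], axis=1)
        lo, hi = np.quantile(meds, [alpha / 2, 1 - alpha / 2])
        rows.append(
            {
                "class": str(cls),
                "median": med,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "n_pixels": int(len(x)),
            }
        )
    return pd.DataFrame(rows).set_index("class")
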