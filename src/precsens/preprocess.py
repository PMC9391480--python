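"""De-seasonalizing, detrending, masking, lag aggregation, aridity classes.

Anomalies are computed in two steps: subtract the month-of-year climatology,
then remove a single ordinary-least-squares linear trend fitted over all
valid months.  Missing months are carried as NaN throughout and never enter
a climatology or a trend fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import AlignmentError, InsufficientDataError, InvalidSpecError

#: The six supported precipitation lag windows, as offsets (in months,
#: relative to the target month t) whose anomalies are averaged.
LAG_WINDOWS: dict[str, tuple[int, ...]] = {
    "m0": (0,),
    "m0:m-1": (0, -1),
    "m0:m-2": (0, -1, -2),
    "m0:m-3": (0, -1, -2, -3),
    "m-1": (-1,),
    "m-1:m-2": (-1, -2),
}

#: Default lag window: the previous month's precipitation anomaly.
DEFAULT_LAG_WINDOW = "m-1"

MIN_VALID_MONTHS = 24


def _require_monthly_series(series: pd.Series) -> pd.Series:
    if not isinstance(series, pd.Series):
        series = pd.Series(series)
    if not isinstance(series.index, pd.DatetimeIndex):
        idx = pd.date_range("1981-01", periods=len(series), freq="MS")
        series = pd.Series(series.to_numpy(), index=idx)
    return series


def climatology(series: pd.Series) -> pd.Series:
    """Month-of-year means over valid data.

    Requires at least :data:`MIN_VALID_MONTHS` valid months and at least one
    valid observation in every calendar month.
    """
    series = _require_monthly_series(series)
    valid = series.dropna()
    if len(valid) < MIN_VALID_MONTHS:
        raise InsufficientDataError(
            f"need >= {MIN_VALID_MONTHS} valid months, got {len(valid)}"
        )
    by_month = valid.groupby(valid.index.month).mean()
    missing = sorted(set(range(1, 13)) - set(by_month.index))
    if missing:
        raise InsufficientDataError(
            f"calendar months entirely missing from the record: {missing}"
        )
    return by_month.reindex(range(1, 13))


def _seasonal_trend_design(index: pd.DatetimeIndex, detrend: bool,
                           t_offset: float = 0.0) -> np.ndarray:
    """Design matrix [intercept, linear time, month dummies (11)]."""
    n = len(index)
    t = t_offset + np.arange(n, dtype=float)
    cols = [np.ones(n)]
    if detrend:
        cols.append(t)
    month = index.month.to_numpy()
    for m in range(2, 13):
        cols.append((month == m).astype(float))
    return np.column_stack(cols)


def anomalies(series: pd.Series, detrend: bool = True) -> pd.Series:
    """De-seasonalized, detrended anomalies of a monthly series.

    The anomaly is the residual of a single least-squares projection onto
    an intercept, a linear time term and month-of-year intercepts, fitted
    jointly over valid months.  Removing the climatology and the trend
    sequentially (in either order) leaves a yearly staircase when the other
    component is present; the joint projection maps a pure linear ramp and
    a pure seasonal cycle exactly to zero and is idempotent.  Output has
    mean ~ 0 and zero linear trend over valid months; invalid months stay
    NaN.  ``detrend=False`` drops the linear time term (de-seasonalize
    only).
    """
    series = _require_monthly_series(series)
    climatology(series)  # validates coverage of every calendar month
    vals = series.to_numpy(dtype=float)
    ok = np.isfinite(vals)
    X = _seasonal_trend_design(series.index, detrend)
    coef, *_ = np.linalg.lstsq(X[ok], vals[ok], rcond=None)
    out = np.full_like(vals, np.nan)
    out[ok] = vals[ok] - X[ok] @ coef
    return pd.Series(out, index=series.index)


class AnomalyTransformer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: monthly climatology + linear trend removal.

    Operates column-wise on a DataFrame with a monthly DatetimeIndex.  ``fit``
    stores the per-column climatology and trend coefficients; ``transform``
    subtracts them, so anomalies of new data are taken relative to the
    training record (and the transform is idempotent on its training data up
    to numerical tolerance).
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = self._as_frame(X)
        self.columns_ = list(X.columns)
        self.coef_ = {}
        design = _seasonal_trend_design(X.index, detrend=True)
        for c in X.columns:
            climatology(X[c])  # validates monthly coverage
            vals = X[c].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            self.coef_[c], *_ = np.linalg.lstsq(design[ok], vals[ok], rcond=None)
        self.n_features_in_ = len(self.columns_)
        self._fit_index = X.index
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = self._as_frame(X)
        design = _seasonal_trend_design(
            X.index, detrend=True, t_offset=self._month_offset(X.index)
        )
        out = {}
        for c in self.columns_:
            out[c] = X[c] - design @ self.coef_[c]
        return pd.DataFrame(out, index=X.index)

    def _month_offset(self, index: pd.DatetimeIndex) -> float:
        base = self._fit_index[0]
        return 12.0 * (index[0].year - base.year) + (index[0].month - base.month)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.Series):
            X = X.to_frame()
        if not isinstance(X, pd.DataFrame) or not isinstance(
            X.index, pd.DatetimeIndex
        ):
            raise InvalidSpecError(
                "AnomalyTransformer requires a DataFrame with a DatetimeIndex"
            )
        return X


def mask_cold_months(ndvi: pd.Series, temperature: pd.Series) -> pd.Series:
    """Mask greenness where air temperature is below zero degC.

    Exactly 0 degC is retained (the filter is a strict inequality, to match
    the below-freezing snow-contamination rationale).
    """
    if len(ndvi) != len(temperature):
        raise AlignmentError(
            f"length mismatch: ndvi {len(ndvi)} vs temperature {len(temperature)}"
        )
    t = np.asarray(temperature, dtype=float)
    return ndvi.where(pd.Series(t >= 0.0, index=ndvi.index))


def lagged_precip_anomaly(prec_anom: pd.Series, window: str) -> pd.Series:
    """Aggregate precipitation anomalies over a lag window.

    The value at month t is the mean anomaly over the window's offsets
    relative to t; leading months where the window reaches before the record
    are NaN.
    """
    if window not in LAG_WINDOWS:
        raise InvalidSpecError(
            f"unknown lag window {window!r}; choose from {sorted(LAG_WINDOWS)}"
        )
    prec_anom = _require_monthly_series(prec_anom)
    offsets = LAG_WINDOWS[window]
    stacked = np.stack([prec_anom.shift(-off).to_numpy() for off in offsets])
    return pd.Series(stacked.mean(axis=0), index=prec_anom.index)


def aridity_class(aridity_index, threshold: float = 0.65):
    """Classify aridity-index values into 'dryland' (< threshold) or
    'non-dryland' (>= threshold, boundary inclusive on the wet side)."""
    ai = np.asarray(aridity_index, dtype=float)
    if np.any(~(ai > 0)):
        raise InvalidSpecError("aridity index must be > 0")
    labels = np.where(ai < threshold, "dryland", "non-dryland")
    if np.isscalar(aridity_index) or ai.ndim == 0:
        return str(labels if labels.ndim == 0 else labels.item())
    return labels


@dataclass
class AnomalyBundle:
    """Aligned anomaly series for one pixel, ready for regression.

    ``prec`` is already aggregated to ``lag_window`` and aligned so that its
    value at month t is the regressor for the greenness anomaly at t.  The
    mask is False wherever any series in use is missing.
    """

    ndvi: pd.Series
    prec: pd.Series
    temp: pd.Series | None
    cloud: pd.Series | None
    mask: pd.Series
    lag_window: str

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.ndvi.index

    def frame(self, multivariate: bool = True) -> pd.DataFrame:
        """Regression frame: target ``ndvi`` plus regressors, masked rows NaN.

        Regressors: the lag-window precipitation anomaly, (optionally)
        current-month temperature and cloud anomalies, and the lag-1
        greenness anomaly.
        """
        cols = {"ndvi": self.ndvi, "prec": self.prec}
        if multivariate:
            if self.temp is None or self.cloud is None:
                raise InvalidSpecError(
                    "multivariate design requires temperature and cloud anomalies"
                )
            cols["temp"] = self.temp
            cols["cloud"] = self.cloud
        cols["ndvi_lag1"] = self.ndvi.shift(1)
        df = pd.DataFrame(cols)
        return df.where(self.mask, np.nan)


def make_anomaly_bundle(
    series: pd.DataFrame,
    lag_window: str = DEFAULT_LAG_WINDOW,
    mask_cold: bool = True,
    standardize: bool = False,
) -> AnomalyBundle:
    """Build the anomaly bundle consumed by the sensitivity estimators.

    Applies (optionally) the cold-month mask to greenness, computes
    de-seasonalized detrended anomalies per variable, aggregates the
    precipitation anomaly to ``lag_window``, and derives the joint validity
    mask.  With ``standardize`` the driver anomalies are scaled to unit
    variance (coefficients then read as greenness change per driver SD).
    """
    required = {"ndvi", "prec"}
    if not required <= set(series.columns):
        raise InvalidSpecError(f"series must contain columns {sorted(required)}")
    ndvi = series["ndvi"]
    if mask_cold and "temp" in series:
        ndvi = mask_cold_months(ndvi, series["temp"])

    def _anom(s: pd.Series) -> pd.Series:
        a = anomalies(s)
        if standardize:
            sd = float(a.std(ddof=1))
            if sd > 0:
                a = a / sd
        return a

    a_ndvi = anomalies(ndvi)
    a_prec = _anom(series["prec"])
    x_prec = lagged_precip_anomaly(a_prec, lag_window)
    a_temp = _anom(series["temp"]) if "temp" in series else None
    a_cloud = _anom(series["cloud"]) if "cloud" in series else None

    mask = a_ndvi.notna() & x_prec.notna()
    for extra in (a_temp, a_cloud):
        if extra is not None:
            mask &= extra.notna()
    return AnomalyBundle(
        ndvi=a_ndvi,
        prec=x_prec,
        temp=a_temp,
        cloud=a_cloud,
        mask=mask,
        lag_window=lag_window,
    )
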