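"""Greenness variability attributed to precipitation.

The precipitation-attributed greenness anomaly is the monthly product of
the sensitivity coefficient and the (lagged) precipitation anomaly; its
moving-window standard deviation is the variability measure whose
normalized trend is compared with the trend in precipitation variability
itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AlignmentError, InvalidSpecError, NormalizationError
from .dlm import sensitivity_trend

#: Moving-window lengths (months): 5 and 9 years.
ALLOWED_WINDOWS = (60, 108)


def contribution_series(theta: pd.Series, prec_anom: pd.Series) -> pd.Series:
    """Monthly precipitation contribution to the greenness anomaly.

    Elementwise product theta_t x dPrec_t; defined only where both inputs
    are valid.  ``theta`` may be a scalar (static sensitivity) or a monthly
    trajectory aligned with ``prec_anom``.
    """
    if np.isscalar(theta):
        return float(theta) * prec_anom
    if len(theta) != len(prec_anom):
        raise AlignmentError(
            f"length mismatch: theta {len(theta)} vs prec {len(prec_anom)}"
        )
    if isinstance(theta, pd.Series) and isinstance(prec_anom, pd.Series):
        if not theta.index.equals(prec_anom.index):
            raise AlignmentError("theta and precipitation anomaly indexes differ")
    return pd.Series(
        np.asarray(theta, dtype=float) * np.asarray(prec_anom, dtype=float),
        index=prec_anom.index if isinstance(prec_anom, pd.Series) else None,
    )


def moving_std(
    series: pd.Series, window_months: int = 60, allow_any_window: bool = False
) -> pd.Series:
    """Centered moving-window sample standard deviation.

    Only full windows are evaluated (months whose centered window would run
    off the record are NaN), avoiding endpoint bias in downstream trend
    fits.  The window must be 60 or 108 months unless explicitly overridden.
    """
    if window_months not in ALLOWED_WINDOWS and not allow_any_window:
        raise InvalidSpecError(
            f"window must be one of {ALLOWED_WINDOWS} months "
            "(pass allow_any_window=True to override)"
        )
    series = pd.Series(series)
    if window_months > len(series):
        raise InvalidSpecError(
            f"window ({window_months}) exceeds series length ({len(series)})"
        )
    return series.rolling(window_months, center=True, min_periods=window_months).std(
        ddof=1
    )


def variability_trends(
    sigma_ndvi_prec: pd.Series,
    sigma_prec: pd.Series,
    n_boot: int = 0,
    seed: int = 0,
) -> dict:
    """Paired normalized trends (% per year) of the two variability series.

    Both series are restricted to their common valid support before the
    trends are fitted, so the comparison is like for like.  Raises
    :class:`NormalizationError` if either series has ~ zero mean.
    """
    a = pd.Series(sigma_ndvi_prec)
    b = pd.Series(sigma_prec)
    common = a.notna() & b.notna()
    if common.sum() < 24:
        raise InvalidSpecError("fewer than 24 months of common valid support")
    try:
        res_a = sensitivity_trend(a[common], n_boot=n_boot, seed=seed)
        res_b = sensitivity_trend(b[common], n_boot=n_boot, seed=seed + 1)
    except NormalizationError:
        raise
    return {
        "sigma_ndvi_prec": res_a,
        "sigma_prec": res_b,
        "ndvi_trend_pct_yr": res_a.normalized_pct_yr,
        "prec_trend_pct_yr": res_b.normalized_pct_yr,
    }
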