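"""NetCDF/CSV readers and writers shared by the pipeline stages.

Gridded data travel as NetCDF (scipy backend, classic format) with CF-style
names and time encoded as months since the generator epoch; tidy tables are
CSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import xarray as xr

_ENGINE = "scipy"


def save_grid(ds: xr.Dataset, path) -> Path:
    """Write a gridded dataset as classic NetCDF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    enc = {}
    if "time" in ds.coords:
        enc["time"] = {"units": "days since 1970-01-01"}
    ds.to_netcdf(path, engine=_ENGINE, encoding=enc)
    return path


def load_grid(path) -> xr.Dataset:
    return xr.open_dataset(path, engine=_ENGINE).load()


def save_table(df: pd.DataFrame, path, index: bool = False) -> Path:
    """Write a tidy table as CSV with stable float formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format="%.10g")
    return path


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def truth_to_frame(ds: xr.Dataset) -> pd.DataFrame:
    """Tidy (pixel, time, theta_prec_true) frame from a synthetic grid."""
    df = ds["theta_prec_true"].to_dataframe().reset_index()
    return df.rename(columns={"theta_prec_true": "theta_prec_true"})
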