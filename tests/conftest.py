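"""Shared fixtures: seeded synthetic inputs with known ground truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import precsens as ps


@pytest.fixture(scope="session")
def climate420() -> pd.DataFrame:
    return ps.make_climate_series(ps.ClimateSpec(n_months=420, seed=11))


@pytest.fixture(scope="session")
def ramp_bundle(climate420):
    """420-month series with a 0.2 -> 0.6 sensitivity ramp at SNR 2."""
    spec0 = ps.SensitivitySpec(
        theta_prec=("ramp", 0.2, 0.6), theta_ndvi=0.3, noise_sd=1.0, seed=12
    )
    nsd = ps.synth.signal_noise_sd(climate420, spec0, snr=2.0)
    spec = dataclasses.replace(spec0, noise_sd=nsd)
    series, truth = ps.make_ndvi_series(climate420, spec)
    return series, truth


@pytest.fixture(scope="session")
def noiseless_bundle(climate420):
    spec = ps.SensitivitySpec(
        theta_prec=0.3, theta_ndvi=0.5, noise_sd=0.0, seed=13
    )
    return ps.make_ndvi_series(climate420, spec)


@pytest.fixture(scope="session")
def scenario_ensemble():
    spec = ps.ScenarioSpec(n_pixels=32, n_models=8, model_spread=0.05, seed=21)
    return spec, ps.make_scenario_ensemble(spec)


@pytest.fixture(scope="session")
def small_transect():
    return ps.make_grid(
        n_pixels=14,
        aridity_range=(0.1, 2.0),
        climate_template=ps.ClimateSpec(n_months=300),
        seed=31,
    )
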