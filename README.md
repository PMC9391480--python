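# precsens

**Time-varying sensitivity of vegetation greenness to precipitation:
estimation, attribution, and a mechanistic CO2 explanation.**

Water availability controls vegetation dynamics over much of the land
surface, and the *sensitivity* of canopy greenness to precipitation —
θ_prec, the regression coefficient of monthly greenness anomalies on
lagged precipitation anomalies — is a first-order descriptor of ecosystem
vulnerability to drought.  Observations show this sensitivity has been
rising in drylands (aridity index < 0.65) and falling in wetter regions
over recent decades.  `precsens` packages the full computational chain
needed to estimate, attribute and explain that contrast:

1. **Estimation** — θ_prec per pixel, statically (multivariate OLS with
   selection among six precipitation lag windows) and dynamically, via a
   discount-factor **dynamic linear model** (DLM): a Kalman-filtered
   state-space regression

       dNDVI_t = theta_NDVI·dNDVI_{t-1} + theta_prec·dPrec_{t-1}
               + theta_temp·dTemp_t + theta_cloud·dCloud_t + eps_t

   whose coefficients drift in time (per-block discount factors), giving
   a monthly posterior trajectory for θ_prec, its normalized trend
   (% yr⁻¹) and bootstrap confidence intervals.
2. **Variability** — the precipitation-attributed greenness variability
   σ(θ_prec·dPrec) in 60/108-month moving windows, compared against
   precipitation variability itself.
3. **Attribution** — factorial scenario differencing (SG1 climate → SG2
   + land use → SG3 + CO2 → BG1 + N deposition) of per-decade regression
   sensitivities, with exact telescoping of factor contributions and
   ensemble mean ± SEM across models.
4. **Mechanism** — a CO2-modified minimalistic ecohydrological model:
   stochastic soil moisture (marked-Poisson rainfall, truncated-gamma
   stationary density), Budyko-style ET partitioning
   E_T/P = f·x̄·φ′·ρ·κ·ζ, stomatal (κ) and leaf-area (ζ) CO2 scalings, a
   CO2-aware Penman–Monteith potential evapotranspiration, and the
   stepwise decomposition of the CO2 effect on ∂LAI/∂P along the aridity
   axis, θ_prec ≈ (∂LAI/∂E_T)(∂E_T/∂P) = (1/(E_L·κ))·∂E_T/∂P.

A synthetic-data module generates every input — climate series, greenness
with prescribed coefficient trajectories, aridity transects, four-scenario
ensembles — with ground truth attached, so the whole chain is testable
offline.  See `docs/methods.md` for the models, defaults and limitations.

## Worked example

Recover a prescribed sensitivity ramp from a single synthetic pixel:

```python
import dataclasses
import numpy as np
import precsens as ps

# a 35-year monthly pixel whose true sensitivity ramps 0.2 -> 0.6,
# with noise fixed at signal-to-noise ratio 2
clim = ps.make_climate_series(ps.ClimateSpec(n_months=420, seed=11))
spec = ps.SensitivitySpec(theta_prec=("ramp", 0.2, 0.6), theta_ndvi=0.3, seed=12)
spec = dataclasses.replace(
    spec, noise_sd=ps.synth.signal_noise_sd(clim, spec, snr=2.0))
series, truth = ps.make_ndvi_series(clim, spec)

bundle = ps.make_anomaly_bundle(series, standardize=True)
model = ps.dlm_fit(bundle)                  # multivariate discount DLM
theta = model.theta("prec")                 # smoothed monthly trajectory
rmse = float(np.sqrt(np.nanmean((theta - truth["theta_prec"])**2)))
trend = ps.sensitivity_trend(theta, n_boot=1000, seed=0)
print(f"trajectory RMSE vs truth: {rmse:.3f}")
print(f"normalized trend: {trend.normalized_pct_yr:.2f} %/yr "
      f"(95% CI {trend.ci_low:.2f} to {trend.ci_high:.2f})")

from precsens import ecohydro as ec
out = ec.co2_effect_decomposition()         # 27-member parameter ensemble
print(f"CO2 effect sign change at aridity index {out['sign_change_aridity']:.2f}")
print("PET-pathway share of the direct effects:",
      {k: round(v, 1) for k, v in out["pet_share_pct"].items()})
```

which prints:

```
trajectory RMSE vs truth: 0.071
normalized trend: 1.12 %/yr (95% CI 1.08 to 1.16)
CO2 effect sign change at aridity index 0.80
PET-pathway share of the direct effects: {'dryland': 0.7, 'non-dryland': 4.4}
```

The trajectory tracks the prescribed ramp to RMSE 0.07 (coefficients are
per standard deviation of the driver anomaly).  The recovered normalized
trend is positive, as prescribed, though shrunk relative to the generating
2.86 %/yr by the smoother's long memory — signs and regional contrasts are
robust, absolute magnitudes are conservative (see `docs/methods.md`).  In
the mechanistic model the full CO2 effect on sensitivity is positive on
the dry side of aridity ≈ 0.8 and negative on the wet side, and the
potential-evapotranspiration pathway contributes only a few percent of
the stomatal + leaf-area pathways.

There is also a CLI for the end-to-end pipelines:

```bash
precsens all --seed 3 --out runs/demo        # simulate -> ... -> ecohydro
precsens ecohydro --out runs/mech            # mechanistic model only
```

Each run writes tidy CSV/NetCDF artifacts plus the resolved configuration,
and identical seeds reproduce byte-identical outputs.

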