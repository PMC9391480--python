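# Methods

`precsens` implements a chain of three analyses around one scientific
question: how does the sensitivity of vegetation greenness to precipitation
change over time, and why does it rise in drylands while falling in wet
regions?  This note records the models, the defaults and their rationale,
the numerical choices, and what the synthetic experiments do and do not
demonstrate.

## 1. The sensitivity model

Monthly greenness anomalies (NDVI or LAI) are modelled as a lag-1
autoregression on climate anomalies:

    dNDVI_t = theta_NDVI * dNDVI_{t-1} + theta_prec * dPrec_{t-1}
            + theta_temp * dTemp_t + theta_cloud * dCloud_t + eps_t

`theta_prec`, the coefficient on the lagged precipitation anomaly, is the
precipitation sensitivity.  Anomalies (`d`) are residuals of a single
least-squares projection onto an intercept, a linear time term and twelve
month-of-year intercepts, computed jointly: sequential removal of a monthly
climatology and then a linear trend (or the reverse) leaves a yearly
staircase whenever the other component is present, whereas the joint
projection maps a pure ramp and a pure seasonal cycle exactly to zero and
is idempotent.  Greenness is masked where air temperature is below 0 °C
(snow contamination; exactly 0 °C is retained).  Six precipitation lag
windows are supported (current month; current plus previous 1, 2 or 3;
previous month; previous two months); the previous-month window is the
default, and the static estimator selects among all six by the coefficient
of determination of the fit (AIC optionally).

### Static estimator

`StaticSensitivity` fits ordinary least squares per lag window (with or
without the temperature/cloud terms) and reports the precipitation
coefficient of the best window with its standard error.  Designs with a
smallest singular value below 1e-10 of the largest raise a collinearity
error.

### Dynamic estimator

`DynamicLinearRegression` is a Gaussian state-space regression estimated by
Kalman filtering.  The state stacks a local level (order-2 local trend
optional), seasonal Fourier harmonics, and a regression block over the
anomaly drivers; each block's one-step prior covariance is inflated by a
per-block discount factor `delta` in (0, 1] (the standard discount
construction of evolution noise), and the observation variance is learned
online with a discounted inverse-gamma recursion.  A fixed-interval
smoother provides the retrospective coefficient trajectory, which is the
reported one (the filtered path is also exposed).

Defaults, all configurable:

| parameter | default | rationale |
|---|---|---|
| trend discount | 0.98 | slow drift of the level of the anomaly process |
| seasonal discount | 0.99 | near-static residual seasonality |
| regression discount | 0.995 | coefficients drift over decades, not months |
| observation-variance discount | 0.99 | standard slowly-adapting variance |
| harmonics | 2 | residual seasonality after anomaly construction is weak |
| prior coefficient covariance | 10 x I (standardized scale) | see below |

Regressors are standardized internally and coefficients reported on both
scales.  The prior is deliberately *weakly informative*, not diffuse: with
discounting, the evolution noise is proportional to the current state
covariance, so a huge prior covariance (e.g. 1e4) injects enormous early
evolution noise and the smoothed trajectory at early months collapses onto
the first few observations.  Coefficients on the standardized scale are
O(1), so a prior variance of 10 is conservative while keeping the early
trajectory identified.  With unit discounts, no trend/seasonal blocks and a
genuinely diffuse prior the filter reproduces batch least squares to 1e-6
relative — the oracle the test suite holds it to.

### Trends

The normalized trend of a coefficient trajectory is the OLS slope per year
divided by the record mean, times 100 (% yr^-1); Theil–Sen is available.
Confidence intervals come from a block bootstrap that resamples whole
years of fit residuals (preserving within-year dependence).  Regional
statistics are medians over pixels with percentile-bootstrap CIs (5000
resamples by default).  Note that the smoothed trajectory's slope is
shrunk toward zero by the coefficient prior and the long discount memory
(roughly 1/(1-delta) months), so estimated normalized trends are
conservative relative to the generating values; their sign and ordering
are robust, and the recovery experiments quantify the effect.

## 2. Variability attribution

The precipitation-attributed greenness anomaly is `theta_prec(t) x
dPrec(t)`; its centered moving-window standard deviation (60 or 108
months, full windows only, avoiding endpoint bias in trend fits) is
compared with the same moving standard deviation of the precipitation
anomaly itself.  Both normalized trends are computed on the common valid
support.  With a static true sensitivity the two trends coincide up to
sampling error; a rising sensitivity makes the attributed-variability
trend less negative than the precipitation-variability trend — the
offsetting effect the analysis is designed to expose.

## 3. Factorial attribution

Four-scenario ensembles (SG1 climate only; SG2 + land use; SG3 + CO2; BG1
+ nitrogen deposition, cumulative) are differenced per model: climate =
SG1, land use = SG2 − SG1, CO2 = SG3 − SG2, nitrogen deposition =
BG1 − SG3, so the contributions telescope exactly to BG1 for each model.
Models missing a scenario have that factor marked unavailable, never zero.
The regional statistic is the median over pixels within each aridity class
per model, then mean and standard error of the mean across models.

Per-decade sensitivities are multivariate regressions of LAI on the lagged
precipitation anomaly, temperature and radiation anomalies and the lag-1
LAI anomaly, one per decade.  Two estimator details matter and are
verified by noiseless recovery tests:

- **Seasonality is absorbed by per-decade month intercepts** in the
  regression rather than by removing a record-wide monthly climatology
  from the target: sample month means couple the decades (they induce
  same-calendar-month correlations of order 1/n_years across the record)
  and demonstrably shrink the decadal trend toward zero; per-decade month
  intercepts attenuate all decades by the same factor, which cancels in
  the normalized trend.
- **Decadal coefficients are located at their effective centres** — the
  driver-weighted mean time with weights x·x̃ (x̃ the precipitation
  regressor residualized on the other regressors), which is where OLS
  localizes a linearly drifting coefficient — rather than at calendar
  midpoints.  Calendar centres remain available for sensitivities that
  are constant within decades.

The chain decomposition estimates dLAI/dE_T, dE_T/dE and dE/dP by separate
univariate anomaly regressions on a common month set; zero-variance
regressors flag the component undefined.  On linear synthetic cascades the
product of the three matches the direct LAI-on-P regression (median error
well under 10% at substantial noise).

## 4. The CO2-modified minimalistic ecohydrological model

Rainfall is a marked Poisson process (frequency `lambda` d^-1, exponential
depths of mean `alpha` mm).  Interception censors each event by a
threshold `Delta`, leaving throughfall events at rate `lambda*rho`,
`rho = exp(-Delta/alpha)`, with the same exponential depths.  The bucket
has plant-available storage `w0` (rooting depth × available water
capacity) and linear losses `E_max * x` in the effective saturation `x`.
The stationary density of `x` is the gamma form with shape
`lambda*rho*w0/E_max` and rate `w0/alpha`, truncated and renormalized on
[0, 1] via the regularized lower incomplete gamma function; overflow is
runoff.  An event-exact Monte-Carlo bucket simulator (exact event times
within days, exact exponential decay between events) serves as the
independent oracle: across a 27-member parameter grid the analytic mean
saturation and ET fractions agree within 1–2% at 1e5 simulated days.  For
slow-mixing members (large `w0/E_max`) the empirical distribution at that
length carries Kolmogorov–Smirnov noise of order 0.03 from
autocorrelation, so the distribution-level check is run on a fast-mixing
member (KS < 0.02).

Evapotranspiration partitions as interception (1 − rho), plus soil
evaporation and transpiration, which split `E_max * x_bar` by the
transpiration share `f`.  `f` is a smooth nondecreasing function of the
mean saturation with a vegetated-fraction parameter,
`f = f_max * (1 - exp(-k x_bar)) / (1 - exp(-k))` by default (`f_max`
0.8, `k` 3) — drier climates support less vegetation cover, so less of
the vaporized water passes through plants.  Two alternative forms (power
and linear in `x_bar`) are provided, and the CO2-contrast conclusions are
verified to hold under all three.  The transpiration fraction of
precipitation is `E_T/P = f * x_bar * phi' * rho` with
`phi' = E_max/(lambda*rho*alpha)` the interception-adjusted dryness.

### CO2 pathways

Elevated CO2 enters through four switchable pathways:

1. **Stomatal closure on transpiration** — the conductance ratio `kappa`
   scales the evaporative demand the soil-moisture balance sees, so
   `x_bar`, `phi'` (and hence `E_T/P = f x_bar phi' rho kappa ...` in the
   water-limited limit, where the demand scaling reduces to the plain
   product) all respond.  A plain multiplicative `kappa` with no
   water-balance feedback would be cancelled exactly by pathway 3 and
   could never produce the wet-end sensitivity decline; the demand
   formulation is what makes the dry/wet contrast emerge.
2. **LAI enhancement on transpiration** — `zeta(AI) >= 1` scales both the
   demand and the transpiration share (more leaves transpire a larger
   fraction and demand more water).
3. **Stomatal closure on transpiration per leaf area** — `E_L` is scaled
   by `kappa`, so dLAI/dE_T = 1/(E_L * kappa) rises by exactly 1/kappa
   (a universal water-use-efficiency gain).
4. **CO2 on potential evapotranspiration** — a CO2-aware Penman–Monteith
   form multiplies the surface-resistance term by
   `0.34 + 2.4e-4([CO2]-300)`; the PET ratio between CO2 levels rescales
   the demand.  Inputs are accepted in Pa K^-1 and W m^-2 and converted
   internally to the FAO convention (kPa, MJ m^-2 d^-1) implied by the
   0.408 radiation coefficient, yielding mm d^-1.

The transpiration share `f` is evaluated at the *reference* climate's
`x_bar` (cover is climatological and responds to CO2 only through
`zeta`); evaluating it at the CO2-perturbed soil moisture would make
stomatal closure raise dryland cover by itself and blur the pathway
decomposition.

`kappa` is the conductance ratio of an optimal-stomata model, `g ~ A/Ca`
with a saturating assimilation response — hyperbolic with a 40 ppm
compensation-point scale for C3, near-saturated (30 ppm half-saturation)
for C4 — so `kappa(C4) <= kappa(C3)` and `kappa` decreases strictly in
elevated CO2.  `zeta = 1 + 1.5 * (dCO2/CO2_ref) * exp(-AI/0.7)`: linear in
the relative CO2 increase, decaying along the aridity index, sized so a
354→384 ppm step gives ~9% LAI enhancement at AI 0.2 and ~1.5% at AI 1.5,
consistent in magnitude with free-air CO2 enrichment syntheses (strong in
drylands, small in wet climates).  Both scalings are injectable.

### Sensitivity curve and decomposition

`theta_prec ~ dLAI/dP = (1/(E_L kappa)) dE_T/dP`, with dE_T/dP a central
finite difference under a 1% relative perturbation of the mean event depth
at fixed event frequency (perturbing the frequency instead is available;
the curve's interior maximum holds under both).  Halving the step changes
the curve by < 0.1%.  The parameter ensemble is 3 soil textures (available
water capacity 70/140/180 mm m^-1) × 3 rooting depths (0.3/0.7/1.5 m) × 3
rainfall depths (5/10/15 mm), with loam/0.7 m/10 mm flagged as the global
land-mean member; `E_max` defaults to the Penman–Monteith value at the
reference climate (4.55 mm d^-1 at 354 ppm) and `E_L` to 0.8 mm d^-1 per
unit LAI.  The stepwise decomposition evaluates
`Delta(dLAI/dP)` between 354 and 384 ppm for cumulative pathway sets,
reports ensemble mean ± SD along the aridity axis, the aridity of the
full-effect sign change (~0.8 with the defaults — positive dry side,
negative wet side), and the PET-pathway share of the direct (stomatal +
LAI) effects per aridity class (well under one order of magnitude of the
direct effects: ~0.7% dryland, ~4.4% non-dryland with the defaults).

## 5. Synthetic data

The generator produces exactly the structures the estimators consume, with
ground truth stored alongside: monthly climate (gamma-distributed
precipitation with a multiplicative seasonal cycle, lognormal interannual
factor and Gaussian-copula AR(1); temperature and cloud with additive
cycles and AR(1) noise), greenness from the lag-1 anomaly recursion with
prescribed constant/ramp/piecewise coefficient trajectories (coefficients
are per standard deviation of the driver anomaly, keeping them comparable
across pixels), a 1-D aridity transect (the analyses are aridity-binned;
a lat/lon map would add only bookkeeping) whose default prescribed
normalized trends are +0.624 % yr^-1 for dryland pixels and −0.618 % yr^-1
for non-dryland pixels, and four-scenario ensembles with additive factor
effects on the sensitivity trend (defaults: climate +0.2, land use +0.1,
CO2 +0.6 dryland / −0.6 non-dryland, nitrogen deposition +0.15 % yr^-1)
sharing one climate forcing so scenario differences isolate the effects
exactly, with `E_T = E_L * LAI` and `E_T <= E` by construction.

What the synthetic experiments do **not** emulate: spatial autocorrelation,
sensor/orbital artifacts, missing-data structure of real satellite
records, non-Gaussian greenness noise, and any feedback of vegetation on
climate.  Passing recovery tests therefore demonstrates correctness of the
estimators under the stated generative model, not performance on real
archives.  Greenness observational noise is a free parameter
(`noise_sd`); recovery experiments fix it through a signal-to-noise ratio
of 2 on the precipitation-driven component.

## 6. Problem sizes and numerics

Recovery experiments use 420-month records (35 years of monthly data) and
100 replicates; the attribution ensemble uses 32 transect pixels, 8 models
and 31 years; the soil-moisture oracle uses 1e5 simulated days per member.
Kalman updates symmetrize covariances each step and raise a conditioning
error on non-positive forecast variances; the smoother solves against the
stored one-step covariances rather than inverting them.  Incomplete-gamma
normalizations that underflow raise a conditioning error.  ET fractions
pushed outside [0, 1] by extreme ensemble corners are clipped with a
logged warning rather than failing the sweep.  Bootstrap, generator and
Monte-Carlo seeds are explicit everywhere; identical seeds give bitwise
identical outputs, including the CSV artifacts of the pipeline.

## 7. Known limitations

- The DLM reports smoothed trajectories whose trends are shrunk toward
  zero by design; absolute trend magnitudes from the dynamic estimator
  are conservative (signs and class contrasts are robust).
- The soil-moisture solution is the steady-state density; transient
  dynamics exist only in the Monte-Carlo oracle.
- `f`, `kappa` and `zeta` are literature-shaped defaults behind
  interfaces, not calibrated fits; conclusions that depend on them are
  checked for robustness across alternative forms, but their absolute
  values carry the defaults' uncertainty.
- The spatial container is a transect; no area weighting or spatial
  pooling is attempted.
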