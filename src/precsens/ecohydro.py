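"""CO2-modified minimalistic ecohydrological model.

The water balance follows the classic stochastic soil-moisture framework:
rainfall is a marked Poisson process (frequency lambda events/day, depths
exponential with mean alpha mm), canopy interception censors each event by
a threshold Delta (leaving throughfall events at rate lambda*rho with
rho = exp(-Delta/alpha) and the same exponential depths), the bucket has
plant-available storage w0 (mm), and evaporative losses are linear in the
effective saturation x = s/w0 with slope E_max (mm/day).  The stationary
density of x is then a gamma density with shape lambda*rho*w0/E_max and
rate w0/alpha, truncated and renormalized on [0, 1] via the lower
incomplete gamma function; overflow at x = 1 is leakage/runoff.

Evapotranspiration partitions as E = E_I + E_S + E_T: interception is the
censored fraction 1 - rho of rainfall, and the transpiration share of
E_S + E_T is f, a smooth nondecreasing function of the mean saturation
x-bar carrying a vegetated-fraction parameter (drier climates support less
cover, so less of the vaporized water passes through plants).  The
transpiration fraction of precipitation is

    E_T / P = f * x_bar * phi' * rho,

with phi' = E_max / (lambda * rho * alpha) the interception-adjusted
dryness (demand over throughfall supply).

Elevated CO2 enters through four pathways: a stomatal-closure factor kappa
(conductance ratio from an optimal-stomata model) and a LAI-enhancement
factor zeta (largest in dry climates, from free-air CO2 enrichment
syntheses) jointly scale the evaporative demand that the soil-moisture
balance sees, so f, x_bar and phi' all respond; kappa also scales the
transpiration-per-leaf-area E_L that converts transpiration to LAI; and a
CO2-aware Penman-Monteith potential evapotranspiration shifts the dryness
itself.  In the water-limited limit the demand scaling reduces to the
plain product f * x_bar * phi' * rho * kappa * zeta.  The sensitivity of
greenness to precipitation is approximated by

    theta_prec ~ dLAI/dP = (1 / (E_L * kappa)) * dE_T/dP,

with dE_T/dP taken by central finite difference, perturbing the mean event
depth alpha at fixed event frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import product

import numpy as np
from scipy import special

from .errors import ConditioningError, InvalidSpecError

logger = logging.getLogger(__name__)

#: CO2 effect pathway labels.
PATHWAYS = ("stomatal_et", "lai_et", "stomatal_el", "pet")

#: Stepwise pathway combinations mirroring the cumulative-effect curves.
STEPWISE = (
    ("stomatal_et",),
    ("stomatal_et", "lai_et"),
    ("stomatal_et", "lai_et", "stomatal_el"),
    ("stomatal_et", "lai_et", "stomatal_el", "pet"),
)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EcohydroParams:
    """Soil, climate and vegetation parameters of the bucket model.

    alpha : mean rainfall event depth (mm).
    w0 : plant-available storage (mm), rooting depth x available water
        capacity.
    e_max : maximum (potential) evaporative demand (mm/day); the linear
        loss slope at full saturation.
    interception : per-event canopy interception threshold Delta (mm).
    f_max : vegetated fraction — the transpiration share of E_S + E_T that
        a fully wet climate sustains.
    f_shape : curvature of the transpiration-share function f(x_bar).
    e_leaf : transpiration per unit leaf area E_L (mm/day per LAI).
    pathway : photosynthetic pathway, 'C3' or 'C4' (sets the stomatal
        response to CO2).
    """

    alpha: float = 10.0
    w0: float = 98.0
    e_max: float = 4.55
    interception: float = 0.5
    f_max: float = 0.8
    f_shape: float = 3.0
    e_leaf: float = 0.8
    pathway: str = "C3"

    def validate(self) -> None:
        if min(self.alpha, self.w0, self.e_max, self.e_leaf) <= 0:
            raise InvalidSpecError("alpha, w0, e_max, e_leaf must all be > 0")
        if self.interception < 0:
            raise InvalidSpecError("interception threshold must be >= 0")
        if not 0 < self.f_max <= 1:
            raise InvalidSpecError("f_max must lie in (0, 1]")
        if self.pathway not in ("C3", "C4"):
            raise InvalidSpecError("pathway must be 'C3' or 'C4'")

    @property
    def rho(self) -> float:
        """Throughfall fraction exp(-Delta/alpha) for exponential depths."""
        return float(np.exp(-self.interception / self.alpha))


@dataclass(frozen=True)
class CO2Config:
    """Reference/elevated CO2 (ppm) and the enabled effect pathways."""

    co2_ref: float = 354.0
    co2_elev: float = 384.0
    effects: tuple[str, ...] = PATHWAYS

    def validate(self) -> None:
        if self.co2_ref <= 0 or self.co2_elev <= 0:
            raise InvalidSpecError("CO2 mixing ratios must be > 0 ppm")
        unknown = set(self.effects) - set(PATHWAYS)
        if unknown:
            raise InvalidSpecError(
                f"unknown effect pathways: {sorted(unknown)}; valid: {PATHWAYS}"
            )


@dataclass(frozen=True)
class PMInputs:
    """Inputs of the CO2-aware Penman-Monteith potential evapotranspiration.

    delta_svp : slope of the saturation vapour pressure curve (Pa/K).
    rn_star : net radiation adjusted for ground heat flux (W/m2).
    gamma_pc : psychrometric constant (Pa/K, ~66).
    temp : air temperature (degC).
    wind : wind speed at 2 m (m/s).
    vpd : vapour pressure deficit (Pa).
    co2 : CO2 mixing ratio (ppm).
    """

    delta_svp: float = 145.0
    rn_star: float = 150.0
    gamma_pc: float = 66.0
    temp: float = 20.0
    wind: float = 2.0
    vpd: float = 1000.0
    co2: float = 354.0

    def validate(self) -> None:
        if self.delta_svp <= 0:
            raise InvalidSpecError("delta_svp must be > 0")
        if self.vpd < 0 or self.wind < 0:
            raise InvalidSpecError("vpd and wind must be >= 0")


# ---------------------------------------------------------------------------
# stochastic soil moisture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SoilMoistureDist:
    """Stationary distribution of effective saturation on [0, 1].

    Truncated-gamma form: density proportional to x^(shape-1) exp(-rate x),
    normalized by the regularized lower incomplete gamma function.
    """

    shape: float
    rate: float
    norm: float          # P(shape, rate): mass of the untruncated gamma on [0, 1]
    mean: float
    f: float             # transpiration share of E_S + E_T at this climate

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = (
                self.shape * np.log(self.rate)
                + (self.shape - 1.0) * np.log(x)
                - self.rate * x
                - special.gammaln(self.shape)
                - np.log(self.norm)
            )
        out = np.where((x >= 0) & (x <= 1), np.exp(logp), 0.0)
        return out

    def cdf(self, x):
        x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
        return special.gammainc(self.shape, self.rate * x) / self.norm


def _trunc_gamma_mean(shape: float, rate: float) -> float:
    """Mean of a gamma(shape, rate) truncated to [0, 1]."""
    p0 = special.gammainc(shape, rate)
    if p0 <= 0 or not np.isfinite(p0):
        raise ConditioningError(
            f"incomplete-gamma normalization underflow (shape={shape}, rate={rate})"
        )
    p1 = special.gammainc(shape + 1.0, rate)
    return (shape / rate) * p1 / p0


def transpiration_share(x_bar: float, f_max: float, f_shape: float) -> float:
    """Transpiration share f of E_S + E_T as a function of mean saturation.

    Saturating-exponential default: f(x) = f_max * (1 - exp(-k x)) /
    (1 - exp(-k)); smooth, nondecreasing, f(0) = 0 and f(1) = f_max.
    """
    k = f_shape
    return float(f_max * (-np.expm1(-k * x_bar)) / (-np.expm1(-k)))


def transpiration_share_power(x_bar, f_max, f_shape):
    """Alternative share function: f = f_max * x_bar^(1/f_shape)."""
    return float(f_max * x_bar ** (1.0 / f_shape))


def transpiration_share_linear(x_bar, f_max, f_shape):
    """Alternative share function: f = f_max * x_bar (f_shape unused)."""
    return float(f_max * x_bar)


def soil_moisture_dist(
    params: EcohydroParams,
    aridity_index: float,
    demand_scale: float = 1.0,
    f_func=transpiration_share,
) -> SoilMoistureDist:
    """Stationary soil-moisture distribution at one climate point.

    ``aridity_index`` (P/E_P) fixes the rainfall rate via
    P = AI * e_max (mean daily precipitation over baseline demand);
    ``demand_scale`` multiplies the loss slope (CO2 pathways plug in here).
    """
    params.validate()
    if aridity_index <= 0:
        raise InvalidSpecError("aridity index must be > 0")
    if demand_scale <= 0:
        raise InvalidSpecError("demand_scale must be > 0")
    lam = aridity_index * params.e_max / params.alpha
    rho = params.rho
    e_eff = params.e_max * demand_scale
    shape = lam * rho * params.w0 / e_eff
    rate = params.w0 / params.alpha
    x_bar = _trunc_gamma_mean(shape, rate)
    f = f_func(x_bar, params.f_max, params.f_shape)
    return SoilMoistureDist(
        shape=shape,
        rate=rate,
        norm=float(special.gammainc(shape, rate)),
        mean=float(x_bar),
        f=float(f),
    )


# ---------------------------------------------------------------------------
# CO2 scalings
# ---------------------------------------------------------------------------

_GAMMA_STAR = 40.0   # ppm, C3 CO2 compensation point scale
_K_C4 = 30.0         # ppm, half-saturation of the near-saturated C4 response


def _assimilation(co2: np.ndarray, pathway: str) -> np.ndarray:
    """Relative assimilation response to CO2 (saturating, unitless)."""
    c = np.asarray(co2, dtype=float)
    if pathway == "C3":
        return (c - _GAMMA_STAR) / (c + 2.0 * _GAMMA_STAR)
    return c / (c + _K_C4)


def kappa(co2_ref: float, co2_elev: float, pathway: str = "C3") -> float:
    """Stomatal-conductance ratio g_s(elevated) / g_s(reference).

    From an optimal-stomata model, conductance is proportional to
    assimilation over CO2 (the vapour-pressure-deficit term cancels in the
    ratio), so kappa = [A(elev)/A(ref)] * (ref/elev).  Because assimilation
    saturates, kappa < 1 whenever elevated > reference, and the flatter C4
    response yields a stronger closure (smaller kappa) than C3.
    """
    if co2_ref <= 0 or co2_elev <= 0:
        raise InvalidSpecError("CO2 mixing ratios must be > 0 ppm")
    if pathway not in ("C3", "C4"):
        raise InvalidSpecError("pathway must be 'C3' or 'C4'")
    a_ratio = _assimilation(co2_elev, pathway) / _assimilation(co2_ref, pathway)
    return float(a_ratio * co2_ref / co2_elev)


_ZETA_GAIN = 1.5     # relative LAI gain per relative CO2 increase, dry limit
_ZETA_AI_SCALE = 0.7  # e-folding of the enhancement along the aridity index


def zeta(aridity_index, co2_ref: float, co2_elev: float) -> float | np.ndarray:
    """LAI enhancement factor under elevated CO2, largest in dry climates.

    zeta = 1 + gain * (dCO2/CO2_ref) * exp(-AI / scale): the relative
    enhancement decays exponentially along the aridity index, emulating the
    dryland-to-wet contrast of free-air CO2 enrichment syntheses, and is
    linear in the relative CO2 increase.  zeta = 1 when CO2 is unchanged.
    """
    ai = np.asarray(aridity_index, dtype=float)
    if np.any(ai <= 0):
        raise InvalidSpecError("aridity index must be > 0")
    if co2_ref <= 0 or co2_elev <= 0:
        raise InvalidSpecError("CO2 mixing ratios must be > 0 ppm")
    rel = (co2_elev - co2_ref) / co2_ref
    z = 1.0 + _ZETA_GAIN * rel * np.exp(-ai / _ZETA_AI_SCALE)
    return float(z) if np.isscalar(aridity_index) else z


def pet_pm(inp: PMInputs) -> float:
    """CO2-aware Penman-Monteith potential evapotranspiration (mm/day).

    The aerodynamic surface-resistance term grows linearly with CO2 above
    300 ppm (2.4e-4 per ppm), so elevated CO2 lowers potential
    evapotranspiration.  Pa/K and W/m2 inputs are converted internally to
    the FAO convention (kPa/K, MJ/m2/day) implied by the 0.408 radiation
    coefficient.
    """
    inp.validate()
    delta = inp.delta_svp / 1000.0            # kPa/K
    gamma = inp.gamma_pc / 1000.0             # kPa/K
    rn = inp.rn_star * 0.0864                 # MJ m-2 day-1
    d = inp.vpd / 1000.0                      # kPa
    co2_term = 0.34 + 2.4e-4 * (inp.co2 - 300.0)
    denom = delta + gamma * (1.0 + inp.wind * co2_term)
    if denom <= 0:
        raise InvalidSpecError("non-positive Penman-Monteith denominator")
    num = 0.408 * delta * rn + gamma * (900.0 / (inp.temp + 273.0)) * inp.wind * d
    return float(num / denom)


# ---------------------------------------------------------------------------
# ET partition and sensitivity
# ---------------------------------------------------------------------------

def _pathway_scales(
    params: EcohydroParams,
    co2: CO2Config | None,
    pm_inputs: PMInputs | None = None,
) -> tuple[float, float, float]:
    """(demand_scale, f_scale, kappa_el) for the enabled CO2 pathways."""
    if co2 is None:
        return 1.0, 1.0, 1.0
    co2.validate()
    kap = kappa(co2.co2_ref, co2.co2_elev, params.pathway)
    demand = 1.0
    kappa_el = 1.0
    if "stomatal_et" in co2.effects:
        demand *= kap
    if "pet" in co2.effects:
        base = pm_inputs or PMInputs()
        ref = replace(base, co2=co2.co2_ref)
        elev = replace(base, co2=co2.co2_elev)
        demand *= pet_pm(elev) / pet_pm(ref)
    if "stomatal_el" in co2.effects:
        kappa_el = kap
    return demand, 1.0, kappa_el


def et_partition(
    params: EcohydroParams,
    aridity_index: float,
    co2: CO2Config | None = None,
    pm_inputs: PMInputs | None = None,
    f_func=transpiration_share,
) -> dict:
    """Long-term ET partition fractions of precipitation at one climate.

    Returns ``et_frac`` (transpiration E_T/P), ``es_frac`` (soil
    evaporation E_S/P), ``ei_frac`` (interception E_I/P = 1 - rho),
    ``runoff_frac`` (leakage + overflow), plus the underlying ``x_bar``,
    ``f`` and interception-adjusted dryness ``phi_prime``.  Any fraction
    pushed outside [0, 1] by extreme CO2 scalings is clipped with a logged
    warning.
    """
    demand, _, _ = _pathway_scales(params, co2, pm_inputs)
    zeta_f = 1.0
    if co2 is not None and "lai_et" in co2.effects:
        zeta_f = zeta(aridity_index, co2.co2_ref, co2.co2_elev)
        demand *= zeta_f
    dist = soil_moisture_dist(params, aridity_index, demand_scale=demand, f_func=f_func)
    # vegetation cover (the transpiration share) is climatological: it is set
    # by the reference climate and responds to CO2 only through zeta, not
    # through the CO2-perturbed soil moisture
    if demand != 1.0:
        dist_ref = soil_moisture_dist(params, aridity_index, 1.0, f_func=f_func)
    else:
        dist_ref = dist
    rho = params.rho
    lam = aridity_index * params.e_max / params.alpha
    phi_prime = params.e_max * demand / (lam * rho * params.alpha)
    f = min(dist_ref.f * zeta_f, 0.99)
    et_frac = f * dist.mean * phi_prime * rho
    es_frac = (1.0 - f) * dist.mean * phi_prime * rho
    ei_frac = 1.0 - rho
    fractions = {"et_frac": et_frac, "es_frac": es_frac, "ei_frac": ei_frac}
    for name, v in fractions.items():
        if not 0.0 <= v <= 1.0:
            logger.warning("%s = %.4f outside [0, 1]; clipped", name, v)
            fractions[name] = float(np.clip(v, 0.0, 1.0))
    total_evap = sum(fractions.values())
    fractions["runoff_frac"] = max(0.0, 1.0 - total_evap)
    fractions.update(x_bar=dist.mean, f=f, phi_prime=phi_prime, rho=rho)
    return fractions


def transpiration_rate(
    params: EcohydroParams,
    aridity_index: float,
    co2: CO2Config | None = None,
    pm_inputs: PMInputs | None = None,
    f_func=transpiration_share,
) -> float:
    """Mean transpiration E_T in mm/day at one climate point."""
    frac = et_partition(params, aridity_index, co2, pm_inputs, f_func)
    p = aridity_index * params.e_max   # mm/day
    return frac["et_frac"] * p


def lai_sensitivity(
    params: EcohydroParams,
    aridity_grid,
    co2: CO2Config | None = None,
    pm_inputs: PMInputs | None = None,
    rel_step: float = 1e-2,
    perturb: str = "depth",
    f_func=transpiration_share,
) -> np.ndarray:
    """Sensitivity of LAI to precipitation, dLAI/dP, along an aridity grid.

    dE_T/dP is a central finite difference under a relative perturbation of
    the mean event depth alpha at fixed event frequency (``perturb='rate'``
    perturbs the frequency instead); the result is divided by E_L (scaled
    by kappa when the stomatal-E_L pathway is active).  Units: LAI change
    per mm/day of precipitation.
    """
    ai = np.asarray(aridity_grid, dtype=float)
    if np.any(ai <= 0) or np.any(ai > 3):
        raise InvalidSpecError("aridity grid must lie within (0, 3]")
    if not 1e-8 < rel_step < 0.5:
        raise ConditioningError("relative step outside the trustworthy range")
    if perturb not in ("depth", "rate"):
        raise InvalidSpecError("perturb must be 'depth' or 'rate'")
    _, _, kappa_el = _pathway_scales(params, co2, pm_inputs)

    out = np.empty(ai.shape)
    for i, a in np.ndenumerate(ai):
        p0 = a * params.e_max
        if perturb == "depth":
            up = replace(params, alpha=params.alpha * (1 + rel_step))
            dn = replace(params, alpha=params.alpha * (1 - rel_step))
            # fixed event frequency: aridity rescales with the new depth
            lam = a * params.e_max / params.alpha
            ai_up = lam * up.alpha / params.e_max
            ai_dn = lam * dn.alpha / params.e_max
            et_up = transpiration_rate(up, ai_up, co2, pm_inputs, f_func)
            et_dn = transpiration_rate(dn, ai_dn, co2, pm_inputs, f_func)
        else:
            et_up = transpiration_rate(
                params, a * (1 + rel_step), co2, pm_inputs, f_func
            )
            et_dn = transpiration_rate(
                params, a * (1 - rel_step), co2, pm_inputs, f_func
            )
        d_et = (et_up - et_dn) / (2.0 * rel_step * p0)
        if abs(et_up - et_dn) < 1e3 * np.finfo(float).eps * max(abs(et_up), 1e-30):
            raise ConditioningError(
                f"finite-difference step too small at aridity {a:.3f}"
            )
        out[i] = d_et / (params.e_leaf * kappa_el)
    return out


# ---------------------------------------------------------------------------
# parameter ensemble and CO2-effect decomposition
# ---------------------------------------------------------------------------

#: Available water capacity (mm per m of soil) by texture class.
SOIL_AWC = {"sand": 70.0, "loam": 140.0, "clay": 180.0}
ROOTING_DEPTHS_M = (0.3, 0.7, 1.5)
RAIN_DEPTHS_MM = (5.0, 10.0, 15.0)

#: Central "global land mean" member: loam soil, 0.7 m roots, 10 mm events.
CENTRAL_MEMBER = ("loam", 0.7, 10.0)


def parameter_ensemble(base: EcohydroParams | None = None) -> list[dict]:
    """The 3 soils x 3 rooting depths x 3 rainfall depths ensemble.

    Each entry carries the :class:`EcohydroParams` and a ``central`` flag on
    the global-land-mean member.
    """
    base = base or EcohydroParams()
    members = []
    for soil, depth, rain in product(SOIL_AWC, ROOTING_DEPTHS_M, RAIN_DEPTHS_MM):
        params = replace(base, w0=SOIL_AWC[soil] * depth, alpha=rain)
        members.append(
            {
                "soil": soil,
                "rooting_depth_m": depth,
                "rain_depth_mm": rain,
                "params": params,
                "central": (soil, depth, rain) == CENTRAL_MEMBER,
            }
        )
    return members


def co2_effect_decomposition(
    aridity_grid=None,
    members: list[dict] | None = None,
    co2_ref: float = 354.0,
    co2_elev: float = 384.0,
    effect_sets: tuple[tuple[str, ...], ...] | None = None,
    pm_inputs: PMInputs | None = None,
    dryland_threshold: float = 0.65,
    f_func=transpiration_share,
) -> dict:
    """Change in dLAI/dP between CO2 levels for stepwise pathway sets.

    For every parameter-ensemble member and every requested effect set the
    difference curve Delta(AI) = dLAI/dP(elevated) - dLAI/dP(reference) is
    computed along the aridity grid; curves are summarized as ensemble mean
    and standard deviation.  Also reported: the aridity value where the
    full-effect ensemble-mean Delta changes sign, and the PET-pathway share
    of the total absolute effect per aridity class (mean |Delta_pet| over
    mean |Delta_stomatal+LAI|, as a percentage).
    """
    if aridity_grid is None:
        aridity_grid = np.linspace(0.05, 3.0, 60)
    ai = np.asarray(aridity_grid, dtype=float)
    members = members if members is not None else parameter_ensemble()
    effect_sets = effect_sets if effect_sets is not None else ((),) + STEPWISE
    for es in effect_sets:
        unknown = set(es) - set(PATHWAYS)
        if unknown:
            raise InvalidSpecError(f"unknown effect labels: {sorted(unknown)}")

    def _delta(params, effects):
        ref = lai_sensitivity(params, ai, co2=None, f_func=f_func)
        if not effects:
            return np.zeros_like(ref)
        cfg = CO2Config(co2_ref=co2_ref, co2_elev=co2_elev, effects=tuple(effects))
        elev = lai_sensitivity(
            params, ai, co2=cfg, pm_inputs=pm_inputs, f_func=f_func
        )
        return elev - ref

    curves = {}
    for es in effect_sets:
        stack = np.stack([_delta(m["params"], es) for m in members])
        curves[es] = {
            "mean": stack.mean(axis=0),
            "sd": stack.std(axis=0, ddof=1) if len(members) > 1 else 0 * stack[0],
            "members": stack,
        }

    result = {"aridity": ai, "curves": curves, "members": members}

    full = tuple(PATHWAYS)
    if full in curves:
        mean = curves[full]["mean"]
        sign_change = np.flatnonzero(np.diff(np.sign(mean)) != 0)
        result["sign_change_aridity"] = (
            float(ai[sign_change[0] + 1]) if len(sign_change) else float("nan")
        )

    pet_only = ("pet",)
    direct = ("stomatal_et", "lai_et", "stomatal_el")
    need = {pet_only, direct} - set(curves)
    pet_curves = {
        es: curves.get(es)
        or {"members": np.stack([_delta(m["params"], es) for m in members])}
        for es in (pet_only, direct)
    }
    dry = ai < dryland_threshold
    shares = {}
    for cls, sel in (("dryland", dry), ("non-dryland", ~dry)):
        pet_mag = np.abs(pet_curves[pet_only]["members"][:, sel]).mean()
        dir_mag = np.abs(pet_curves[direct]["members"][:, sel]).mean()
        shares[cls] = float(100.0 * pet_mag / dir_mag) if dir_mag > 0 else float("nan")
    result["pet_share_pct"] = shares
    return result


# ---------------------------------------------------------------------------
# Monte-Carlo bucket oracle
# ---------------------------------------------------------------------------

def monte_carlo_bucket(
    params: EcohydroParams,
    aridity_index: float,
    n_days: int = 100_000,
    demand_scale: float = 1.0,
    seed: int = 0,
    burn_in_days: int = 2_000,
) -> dict:
    """Event-exact stochastic simulation of the rainfall-bucket system.

    An explicit reference simulator for the analytic stationary solution:
    each day draws a Poisson number of rainfall events at exact uniform
    times, each with an exponential depth censored by the interception
    threshold; between events the bucket drains exactly along the
    linear-loss exponential, and event overflow is runoff.  Returns the
    time-average saturation, end-of-day saturation samples, and the
    simulated partition fractions.
    """
    params.validate()
    if aridity_index <= 0:
        raise InvalidSpecError("aridity index must be > 0")
    rng = np.random.default_rng(seed)
    lam = aridity_index * params.e_max / params.alpha
    e_eff = params.e_max * demand_scale
    eta = e_eff / params.w0
    total = n_days + burn_in_days

    s = 0.5 * params.w0
    total_et = 0.0
    total_rain = 0.0
    total_intercept = 0.0
    total_runoff = 0.0
    samples = np.empty(n_days)
    counts = rng.poisson(lam, total)
    for day in range(total):
        n_ev = counts[day]
        record = day >= burn_in_days
        if n_ev:
            times = np.sort(rng.random(n_ev))
            depths = rng.exponential(params.alpha, n_ev)
            t_prev = 0.0
            for u, d in zip(times, depths):
                s_dec = s * np.exp(-eta * (u - t_prev))
                if record:
                    total_et += s - s_dec
                s = s_dec
                through = max(d - params.interception, 0.0)
                overflow = max(0.0, s + through - params.w0)
                s = min(s + through, params.w0)
                if record:
                    total_rain += d
                    total_intercept += min(d, params.interception)
                    total_runoff += overflow
                t_prev = u
            s_end = s * np.exp(-eta * (1.0 - t_prev))
        else:
            s_end = s * np.exp(-eta)
        if record:
            total_et += s - s_end
            samples[day - burn_in_days] = s_end / params.w0
        s = s_end

    x_bar_time = total_et / (e_eff * n_days)
    return {
        "x_bar": x_bar_time,
        "samples": samples,
        "esum_frac": total_et / total_rain,          # (E_S + E_T) / P
        "ei_frac": total_intercept / total_rain,
        "runoff_frac": total_runoff / total_rain,
        "p_mean": total_rain / n_days,
    }
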