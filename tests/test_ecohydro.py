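"""Stochastic soil moisture, ET partition, CO2 scalings, sensitivity curves."""

import numpy as np
import pytest
from scipy.integrate import quad

from precsens import ecohydro as ec
from precsens.errors import ConditioningError, InvalidSpecError


@pytest.fixture(scope="module")
def params():
    return ec.EcohydroParams()


class TestSoilMoisture:
    def test_density_normalized_and_mean_in_unit_interval(self, params):
        for ai in np.linspace(0.1, 2.5, 10):
            for scale in (0.8, 1.0, 1.2):
                dist = ec.soil_moisture_dist(params, ai, demand_scale=scale)
                mass, _ = quad(dist.pdf, 0, 1, limit=200)
                assert mass == pytest.approx(1.0, abs=1e-8)
                assert 0.0 < dist.mean < 1.0
                mean, _ = quad(lambda x: x * dist.pdf(x), 0, 1, limit=200)
                assert mean == pytest.approx(dist.mean, abs=1e-8)

    def test_mean_saturation_decreases_with_dryness(self, params):
        # higher demand at fixed rain = larger phi' = drier bucket
        scales = np.linspace(0.6, 2.0, 12)
        means = [
            ec.soil_moisture_dist(params, 0.8, demand_scale=s).mean for s in scales
        ]
        assert np.all(np.diff(means) < 0)

    def test_invalid_inputs_rejected(self, params):
        with pytest.raises(InvalidSpecError):
            ec.soil_moisture_dist(params, -0.5)
        with pytest.raises(InvalidSpecError):
            ec.soil_moisture_dist(params, 0.5, demand_scale=0.0)


class TestMonteCarloOracle:
    def test_fast_mixing_member_matches_mean_and_distribution(self):
        # small storage mixes quickly: 1e5 days give a sharp comparison
        p = ec.EcohydroParams(w0=21.0, alpha=5.0)
        ai = 0.6
        dist = ec.soil_moisture_dist(p, ai)
        mc = ec.monte_carlo_bucket(p, ai, n_days=100_000, seed=0)
        assert abs(mc["x_bar"] - dist.mean) / dist.mean < 0.01
        s = np.sort(mc["samples"])
        n = len(s)
        cdf = dist.cdf(s)
        ks = max(
            np.max(np.abs(np.arange(1, n + 1) / n - cdf)),
            np.max(np.abs(np.arange(n) / n - cdf)),
        )
        assert ks < 0.02

    def test_water_balance_closes(self):
        p = ec.EcohydroParams(w0=42.0, alpha=8.0)
        mc = ec.monte_carlo_bucket(p, 0.8, n_days=60_000, seed=1)
        closure = mc["esum_frac"] + mc["ei_frac"] + mc["runoff_frac"]
        assert closure == pytest.approx(1.0, abs=0.01)

    def test_analytic_et_fraction_matches_simulation_wet_and_dry(self):
        p = ec.EcohydroParams(w0=42.0, alpha=8.0)
        for ai in (0.25, 2.5):
            dist = ec.soil_moisture_dist(p, ai)
            lam = ai * p.e_max / p.alpha
            phi = p.e_max / (lam * p.rho * p.alpha)
            analytic = dist.mean * phi * p.rho       # (E_S + E_T) / P
            mc = ec.monte_carlo_bucket(p, ai, n_days=80_000, seed=2)
            assert abs(mc["esum_frac"] - analytic) / analytic < 0.02


class TestETPartition:
    def test_reference_co2_reduces_to_unmodified_model(self, params):
        import dataclasses
        p0 = dataclasses.replace(params, interception=0.0)   # rho = 1
        out = ec.et_partition(p0, 0.7, co2=None)
        dist = ec.soil_moisture_dist(p0, 0.7)
        assert out["et_frac"] == pytest.approx(
            dist.f * dist.mean * out["phi_prime"], rel=1e-12
        )
        assert out["ei_frac"] == 0.0
        co2_neutral = ec.CO2Config(co2_ref=354.0, co2_elev=354.0)
        out2 = ec.et_partition(p0, 0.7, co2=co2_neutral)
        assert out2["et_frac"] == pytest.approx(out["et_frac"], rel=1e-12)

    def test_fractions_bounded_over_full_sweep(self, params):
        for ai in np.linspace(0.05, 3.0, 30):
            out = ec.et_partition(params, ai, co2=ec.CO2Config())
            for key in ("et_frac", "es_frac", "ei_frac", "runoff_frac"):
                assert 0.0 <= out[key] <= 1.0
            assert out["et_frac"] + out["es_frac"] + out["ei_frac"] <= 1.0 + 1e-9

    def test_partition_ordering_follows_share_function(self, params):
        out = ec.et_partition(params, 1.5)
        # wet climate, large f: transpiration dominates soil evaporation
        assert out["et_frac"] > out["es_frac"]


class TestKappa:
    def test_equal_co2_is_unity(self):
        assert ec.kappa(354.0, 354.0) == pytest.approx(1.0)

    def test_strictly_decreasing_in_elevated_co2(self):
        grid = np.linspace(360.0, 700.0, 30)
        vals = [ec.kappa(354.0, c) for c in grid]
        assert np.all(np.diff(vals) < 0)
        assert all(0 < v < 1 for v in vals)

    def test_c4_closure_stronger_than_c3(self):
        assert ec.kappa(354.0, 384.0, "C4") <= ec.kappa(354.0, 384.0, "C3")

    def test_nonpositive_ppm_rejected(self):
        with pytest.raises(InvalidSpecError):
            ec.kappa(-1.0, 384.0)


class TestZeta:
    def test_equal_co2_is_unity_everywhere(self):
        for ai in (0.1, 0.65, 2.5):
            assert ec.zeta(ai, 354.0, 354.0) == pytest.approx(1.0)

    def test_dry_enhancement_exceeds_wet(self):
        dry = ec.zeta(0.2, 354.0, 384.0) - 1.0
        wet = ec.zeta(1.5, 354.0, 384.0) - 1.0
        assert dry > wet > 0.0

    def test_continuous_along_aridity(self):
        # jumps on a fine grid shrink with the step: no discontinuities
        ai = np.linspace(0.05, 3.0, 4000)
        z = ec.zeta(ai, 354.0, 384.0)
        step = ai[1] - ai[0]
        slope_bound = (z.max() - z.min()) / 0.5   # steepest admissible slope
        assert np.max(np.abs(np.diff(z))) < max(1e-6, 3 * slope_bound * step)
        assert np.all(np.diff(z) <= 0)

    def test_nonpositive_aridity_rejected(self):
        with pytest.raises(InvalidSpecError):
            ec.zeta(0.0, 354.0, 384.0)


class TestPenmanMonteith:
    def test_no_wind_removes_aerodynamic_and_co2_terms(self):
        inp = ec.PMInputs(wind=0.0, co2=354.0)
        expected = (
            0.408 * (inp.delta_svp / 1000) * (inp.rn_star * 0.0864)
            / (inp.delta_svp / 1000 + inp.gamma_pc / 1000)
        )
        assert ec.pet_pm(inp) == pytest.approx(expected, rel=1e-12)
        assert ec.pet_pm(ec.PMInputs(wind=0.0, co2=700.0)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_reference_300ppm_recovers_classic_form(self):
        inp = ec.PMInputs(co2=300.0)
        delta, gamma = 0.145, 0.066
        rn, d, u, t = 150 * 0.0864, 1.0, 2.0, 20.0
        classic = (0.408 * delta * rn + gamma * (900 / (t + 273)) * u * d) / (
            delta + gamma * (1 + 0.34 * u)
        )
        assert ec.pet_pm(inp) == pytest.approx(classic, rel=1e-12)

    def test_hand_computed_values_and_co2_suppression(self):
        # independent hand evaluation at Delta=145 Pa/K, Rn*=150 W/m2,
        # T=20 C, u=2 m/s, D=1000 Pa
        at_354 = ec.pet_pm(ec.PMInputs(co2=354.0))
        at_384 = ec.pet_pm(ec.PMInputs(co2=384.0))
        assert at_354 == pytest.approx(4.5510, abs=2e-3)
        assert at_384 == pytest.approx(4.5343, abs=2e-3)
        assert at_384 < at_354

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(InvalidSpecError):
            ec.PMInputs(delta_svp=-145.0).validate()


class TestSensitivityCurve:
    def test_positive_with_interior_maximum(self, params):
        ai = np.linspace(0.05, 3.0, 50)
        for mode in ("depth", "rate"):
            curve = ec.lai_sensitivity(params, ai, perturb=mode)
            assert (curve > 0).all()
            k = int(np.argmax(curve))
            assert 0 < k < len(ai) - 1
            assert ai[k] < 1.0   # semiarid maximum

    def test_step_refinement_stable(self, params):
        ai = np.linspace(0.1, 2.5, 15)
        c1 = ec.lai_sensitivity(params, ai, rel_step=1e-2)
        c2 = ec.lai_sensitivity(params, ai, rel_step=5e-3)
        assert np.max(np.abs(c2 - c1) / c1) < 1e-3

    def test_out_of_domain_grid_rejected(self, params):
        with pytest.raises(InvalidSpecError):
            ec.lai_sensitivity(params, [0.5, 3.5])
        with pytest.raises(ConditioningError):
            ec.lai_sensitivity(params, [0.5], rel_step=1e-12)


class TestCO2Pathways:
    AI = np.linspace(0.05, 3.0, 40)

    def _curve(self, params, effects):
        if not effects:
            return ec.lai_sensitivity(params, self.AI)
        cfg = ec.CO2Config(effects=effects)
        return ec.lai_sensitivity(params, self.AI, co2=cfg)

    def test_stomatal_pathway_lowers_transpiration_sensitivity(self, params):
        base = self._curve(params, ())
        stoma = self._curve(params, ("stomatal_et",))
        assert (stoma < base).all()

    def test_leaf_pathway_is_exact_inverse_kappa(self, params):
        base = self._curve(params, ())
        leaf = self._curve(params, ("stomatal_el",))
        kap = ec.kappa(354.0, 384.0, "C3")
        np.testing.assert_allclose(leaf, base / kap, rtol=1e-12)

    def test_lai_pathway_relative_gain_largest_when_dry(self, params):
        base = self._curve(params, ())
        lai = self._curve(params, ("lai_et",))
        ratio = lai / base
        assert ratio[0] > 1.0
        assert ratio[0] > ratio[-1]

    def test_pet_pathway_much_smaller_than_others(self, params):
        base = self._curve(params, ())
        pet = np.abs(self._curve(params, ("pet",)) - base)
        rest = np.abs(
            self._curve(params, ("stomatal_et", "lai_et", "stomatal_el")) - base
        )
        dry = self.AI < 0.65
        for sel in (dry, ~dry):
            assert pet[sel].mean() * 5 < rest[sel].mean()

    def test_full_effect_contrasts_dry_and_wet(self, params):
        base = self._curve(params, ())
        full = self._curve(params, ec.PATHWAYS)
        delta = full - base
        assert delta[0] > 0 > delta[-1]
        assert np.sum(np.diff(np.sign(delta)) != 0) >= 1

    def test_c4_gives_larger_dryland_response_than_c3(self, params):
        import dataclasses
        delta = {}
        for pw in ("C3", "C4"):
            p = dataclasses.replace(params, pathway=pw)
            delta[pw] = self._curve(p, ec.PATHWAYS) - self._curve(p, ())
        dry = self.AI < 0.65
        assert delta["C4"][dry].mean() > delta["C3"][dry].mean()

    def test_robust_to_share_function_choice(self, params):
        for f_func in (
            ec.transpiration_share,
            ec.transpiration_share_power,
            ec.transpiration_share_linear,
        ):
            base = ec.lai_sensitivity(params, self.AI, f_func=f_func)
            full = ec.lai_sensitivity(
                params, self.AI, co2=ec.CO2Config(), f_func=f_func
            )
            delta = full - base
            assert delta[0] > 0 > delta[-1]


class TestDecomposition:
    def test_control_is_identically_zero(self):
        out = ec.co2_effect_decomposition(
            aridity_grid=np.linspace(0.1, 2.0, 10), effect_sets=((),)
        )
        np.testing.assert_allclose(out["curves"][()]["mean"], 0.0)

    def test_full_decomposition_summary(self):
        out = ec.co2_effect_decomposition(aridity_grid=np.linspace(0.05, 3.0, 30))
        assert np.isfinite(out["sign_change_aridity"])
        assert 0.2 < out["sign_change_aridity"] < 2.0
        for share in out["pet_share_pct"].values():
            assert 0 < share < 20.0

    def test_unknown_effect_label_rejected(self):
        with pytest.raises(InvalidSpecError):
            ec.co2_effect_decomposition(effect_sets=(("warming",),))


class TestEnsemble:
    def test_grid_has_27_members_with_one_central(self):
        members = ec.parameter_ensemble()
        assert len(members) == 27
        assert sum(m["central"] for m in members) == 1
        central = next(m for m in members if m["central"])
        assert central["soil"] == "loam"
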