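"""Hydrolysis kinetics: rate law, scission, diffusion, swelling, death."""

import numpy as np
import pytest

import stentdeg as sd
from stentdeg.degradation import (
    KineticParams,
    PointState,
    death_check,
    death_probability,
    degradation_rate,
    diffuse_hydrolysates,
    step_beta,
    swelling_state,
)


class TestRateLaw:
    def test_baseline(self, kinetics):
        assert degradation_rate(0.0, 0.0, 1.0, kinetics) == pytest.approx(0.003, rel=1e-12)

    def test_stress_efold(self):
        # 50 MPa at b = 0.02/MPa gives one e-fold: 0.003*e
        p = KineticParams(stress_sensitivity=0.02)
        assert degradation_rate(50.0, 0.0, 1.0, p) == pytest.approx(
            0.003 * np.e, rel=1e-12
        )

    def test_monotone_in_each_factor(self, kinetics):
        base = degradation_rate(5.0, 0.2, 1.05, kinetics)
        assert degradation_rate(6.0, 0.2, 1.05, kinetics) > base
        assert degradation_rate(5.0, 0.3, 1.05, kinetics) > base
        assert degradation_rate(5.0, 0.2, 1.10, kinetics) > base

    def test_negative_concentration_rejected(self, kinetics):
        with pytest.raises(ValueError):
            degradation_rate(0.0, -0.1, 1.0, kinetics)

    @pytest.mark.parametrize("form", ["additive", "exp_all", "mixed"])
    def test_alternative_forms_agree_at_baseline(self, form):
        p = KineticParams(rate_form=form)
        assert degradation_rate(0.0, 0.0, 1.0, p) == pytest.approx(0.003, rel=1e-12)


class TestScission:
    def test_closed_form_180_days(self):
        beta = 1.0
        for _ in range(180):
            beta = step_beta(beta, 0.003, 1.0)
        assert beta == pytest.approx(np.exp(-0.54), rel=1e-12)

    def test_zero_rate_no_change(self):
        assert step_beta(0.7, 0.0, 5.0) == 0.7

    def test_exponential_semigroup(self):
        one = step_beta(step_beta(1.0, 0.01, 2.0), 0.01, 2.0)
        two = step_beta(1.0, 0.01, 4.0)
        assert one == pytest.approx(two, rel=1e-14)


class TestSwelling:
    def test_dry_limit(self, kinetics):
        am, av = swelling_state(0.0, kinetics)
        assert am == 0.0 and av == 1.0

    def test_density_ratio(self):
        # alpha_m = 0.1 with rho_dry/rho_water = 1.2 gives alpha_v = 1.12
        p = KineticParams(alpha_m_inf=0.1, tau_sw=7.0)
        am, av = swelling_state(1e9, p)
        assert am == pytest.approx(0.1, rel=1e-9)
        assert av == pytest.approx(1.12, rel=1e-9)

    def test_monotone_in_time(self, kinetics):
        t = np.linspace(0.0, 60.0, 61)
        av = np.array([swelling_state(x, kinetics)[1] for x in t])
        assert np.all(np.diff(av) >= 0.0)


class TestDeath:
    def test_threshold_kills_deterministically(self, kinetics):
        rng = np.random.default_rng(0)
        alive = death_check(np.array([0.005]), np.array([0.0]), kinetics, rng)
        assert not alive[0]

    def test_per_step_probability_value(self):
        # 1 - exp(-0.12*0.003*1) = 3.5994e-4
        p = death_probability(0.003, 0.12, 1.0)
        assert p == pytest.approx(-np.expm1(-0.00036), rel=1e-12)
        assert p == pytest.approx(3.5994e-4, rel=1e-3)

    def test_monte_carlo_matches_hazard_integral(self, kinetics):
        """Empirical death fraction over 1e6 draws within 3 standard errors
        of the closed-form per-step probability."""
        n = 1_000_000
        rng = np.random.default_rng(12345)
        lam = np.full(n, 0.003)
        alive = death_check(np.ones(n), lam, kinetics, rng)
        p = death_probability(0.003, kinetics.k, kinetics.dt)
        se = np.sqrt(p * (1.0 - p) / n)
        assert abs((~alive).mean() - p) < 3.0 * se

    def test_reproducible_with_seed(self, kinetics):
        a1 = death_check(np.ones(1000), np.full(1000, 5.0), kinetics,
                         np.random.default_rng(7))
        a2 = death_check(np.ones(1000), np.full(1000, 5.0), kinetics,
                         np.random.default_rng(7))
        assert np.array_equal(a1, a2)

    def test_dead_points_stay_dead(self, kinetics):
        rng = np.random.default_rng(0)
        alive = np.array([False, True])
        out = death_check(np.array([0.5, 0.5]), np.zeros(2), kinetics, rng, alive)
        assert not out[0]


class TestDiffusion:
    def test_uniform_field_unchanged(self):
        lat = sd.toy_lattice("cube_graph", 27)
        st = PointState.initial(lat.n_points)
        st.c_m = np.full(lat.n_points, 0.37)
        p = KineticParams(release_coeff=0.0, source_coeff=0.0)
        out = diffuse_hydrolysates(lat, st, p, 1.0)
        assert np.allclose(out, 0.37, atol=1e-14)

    def test_closed_system_mass_conservation(self):
        lat = sd.toy_lattice("cube_graph", 27)
        st = PointState.initial(lat.n_points)
        rng = np.random.default_rng(3)
        st.c_m = rng.random(lat.n_points)
        st.beta = 0.5 + 0.5 * rng.random(lat.n_points)  # non-uniform diffusivity
        V = lat.point_volumes()
        m0 = (st.c_m * V).sum()
        p = KineticParams(release_coeff=0.0, source_coeff=0.0)
        out = diffuse_hydrolysates(lat, st, p, 1.0)
        assert (out * V).sum() == pytest.approx(m0, rel=1e-8)

    def test_source_injection_accounting(self):
        """With no release, the hydrolysate mass gain equals the injected
        source mass tied to chain scission."""
        lat = sd.toy_lattice("single_beam", 5)
        st = PointState.initial(lat.n_points)
        beta_before = np.ones(lat.n_points)
        st.beta = np.full(lat.n_points, 0.95)
        p = KineticParams(release_coeff=0.0, source_coeff=2.0)
        V = lat.point_volumes()
        out = diffuse_hydrolysates(lat, st, p, 1.0, beta_before)
        injected = (2.0 * (beta_before - st.beta) * V).sum()
        assert (out * V).sum() == pytest.approx(injected, rel=1e-8)

    def test_diffusivity_amplification(self, kinetics):
        phi0 = kinetics.phi0
        phi_deg = phi0 * np.exp(kinetics.theta * 1.0)
        assert phi_deg / phi0 == pytest.approx(np.exp(9.43), rel=1e-12)
        assert phi_deg / phi0 == pytest.approx(12453.0, rel=1e-3)

    def test_gradient_relaxes_toward_uniform(self):
        lat = sd.toy_lattice("single_beam", 4, length=1.0)
        st = PointState.initial(lat.n_points)
        # partially degraded material diffuses ~10^3 x faster than intact
        st.beta = np.full(lat.n_points, 0.3)
        st.c_m = np.zeros(lat.n_points)
        st.c_m[0] = 1.0
        p = KineticParams(release_coeff=0.0, source_coeff=0.0)
        out = diffuse_hydrolysates(lat, st, p, 5.0)
        assert out.std() < st.c_m.std()
        assert out[0] < 1.0 and out[-1] > 0.0


class TestStressAcceleration:
    def test_higher_stress_degrades_faster(self, kinetics):
        """beta under sigma1 > sigma2 stays at or below the low-stress curve."""
        b1 = b2 = 1.0
        for _ in range(50):
            b1 = step_beta(b1, degradation_rate(20.0, 0.0, 1.0, kinetics), 1.0)
            b2 = step_beta(b2, degradation_rate(5.0, 0.0, 1.0, kinetics), 1.0)
        assert b1 < b2


def test_kinetic_params_validation():
    with pytest.raises(ValueError):
        KineticParams(lambda0=-0.1)
    with pytest.raises(ValueError):
        KineticParams(rate_form="bogus")
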