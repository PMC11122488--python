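"""Coupled simulation loop: closed-form limits, determinism, indices."""

import numpy as np
import pytest

import stentdeg as sd
from stentdeg.degradation import PointState
from stentdeg.simulate import compute_indices, run

from conftest import zero_stress_kinetics


@pytest.fixture(scope="module")
def zero_stress_run():
    """180-day run with every coupling off: pure first-order hydrolysis."""
    lat = sd.build_lattice(sd.builtin_design("DESolve"), segment_rings=3)
    return run(lat, kinetics=zero_stress_kinetics(), n_days=180)


def test_zero_stress_closed_form(zero_stress_run):
    """With stress, autocatalysis, swelling and death all off, every point
    follows beta(t) = exp(-lambda0 t) to near machine precision."""
    res = zero_stress_run
    expected = np.exp(-0.003 * 180.0)
    assert np.allclose(res.points.beta, expected, rtol=1e-10)
    assert res.series.beta_mean[-1] == pytest.approx(expected, rel=1e-10)
    assert res.points.alive.all()


def test_zero_stress_volume_constant(zero_stress_run):
    assert np.allclose(zero_stress_run.series.v_r, 1.0, atol=1e-12)


@pytest.fixture(scope="module")
def coupled_short_run():
    """30-day coupled run on a 2-ring segment with all couplings on."""
    lat = sd.build_lattice(sd.builtin_design("DESolve"), segment_rings=2)
    return run(
        lat,
        kinetics=sd.KineticParams(seed=7),
        vessel=sd.VesselSpec(),
        balloon=sd.BalloonProgram(),
        waveform=sd.Waveform(),
        n_days=30,
    )


def test_series_shapes_and_start(coupled_short_run):
    s = coupled_short_run.series
    assert len(s.day) == 31
    assert s.v_r[0] == pytest.approx(1.0)
    assert s.beta_mean[0] == pytest.approx(1.0)
    assert np.all(s.D > 0.0)


def test_beta_mean_monotone_decreasing(coupled_short_run):
    assert np.all(np.diff(coupled_short_run.series.beta_mean) < 0.0)


def test_vr_rises_with_swelling(coupled_short_run):
    s = coupled_short_run.series
    assert s.v_r[5] > s.v_r[0]
    assert s.v_r.max() > 1.0


def test_diameter_stable_during_degradation(coupled_short_run):
    """The stent diameter must not grow during degradation beyond model
    tolerance (the modulus only decays)."""
    D = coupled_short_run.series.D
    assert np.all(np.diff(D) < 5e-3)
    assert abs(D[-1] - D[0]) < 5e-3


def test_determinism_same_seed():
    lat = sd.build_lattice(sd.builtin_design("Fantom"), segment_rings=2)
    kw = dict(
        vessel=sd.VesselSpec(), balloon=sd.BalloonProgram(),
        waveform=sd.Waveform(), n_days=5,
    )
    r1 = run(lat, kinetics=sd.KineticParams(seed=3), **kw)
    lat2 = sd.build_lattice(sd.builtin_design("Fantom"), segment_rings=2)
    r2 = run(lat2, kinetics=sd.KineticParams(seed=3), **kw)
    assert np.array_equal(r1.series.beta_mean, r2.series.beta_mean)
    assert np.array_equal(r1.series.v_r, r2.series.v_r)
    assert np.array_equal(r1.points.alive, r2.points.alive)


def test_loading_accelerates_degradation(coupled_short_run):
    """A mechanically loaded stent degrades at least as fast as an
    unloaded one (stress only increases the rate)."""
    lat = sd.build_lattice(sd.builtin_design("DESolve"), segment_rings=2)
    unloaded = run(lat, kinetics=sd.KineticParams(seed=7), n_days=30)
    assert np.all(
        coupled_short_run.series.beta_mean <= unloaded.series.beta_mean + 1e-12
    )


class TestComputeIndices:
    def test_initial_state(self):
        lat = sd.toy_lattice("ring", 8)
        st = PointState.initial(lat.n_points)
        rec = compute_indices(lat, st)
        assert rec["beta_mean"] == 1.0
        assert rec["v_r"] == 1.0

    def test_mean_of_two_levels(self):
        lat = sd.toy_lattice("ring", 8)
        st = PointState.initial(lat.n_points)
        half = lat.n_points // 2
        st.beta[:half] = 0.4
        st.beta[half:] = 0.8
        assert compute_indices(lat, st)["beta_mean"] == pytest.approx(0.6)

    def test_uniform_swelling(self):
        lat = sd.toy_lattice("ring", 8)
        st = PointState.initial(lat.n_points)
        st.alpha_v[:] = 1.12
        assert compute_indices(lat, st)["v_r"] == pytest.approx(1.12)

    def test_dead_points_excluded_from_means(self):
        lat = sd.toy_lattice("ring", 8)
        st = PointState.initial(lat.n_points)
        st.beta[:] = 0.8
        st.beta[0] = 0.1
        st.alive[0] = False
        assert compute_indices(lat, st)["beta_mean"] == pytest.approx(0.8)

    def test_all_dead_still_defines_volume(self):
        lat = sd.toy_lattice("ring", 8)
        st = PointState.initial(lat.n_points)
        st.alive[:] = False
        rec = compute_indices(lat, st)
        assert np.isnan(rec["beta_mean"]) and np.isnan(rec["sigma_mean"])
        assert rec["v_r"] == 0.0  # only alive (swollen) volume counts
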