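"""Coupled mechano-degradation simulation over the implantation period.

Each simulated day the stent is brought to static equilibrium under the
cycle-averaged blood pressure and the artery foundation using the current
(degraded) modulus and yield strength; element stresses are mapped to the
material points; the kinetics then advance the molecular weight, the
hydrolysate field, swelling, and the stochastic death draws; finally the
element properties are refreshed from the point states.  Four daily
indices track the process: mean normalized molecular weight, residual
volume fraction, mean stress, and stent diameter.

The pulsatile pressure amplitude enters the daily loop only through the
fatigue strength-reduction coefficient of the material law; the daily
mechanical load is the cycle average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import degradation as deg
from . import material as mat
from .degradation import KineticParams, PointState
from .geometry import BeamLattice, StentDesign, build_lattice
from .loading import BalloonProgram, VesselSpec, Waveform, mean_pressure
from .mechanics import (
    Constraints,
    ExpandResult,
    LoadCase,
    MechState,
    SolverParams,
    _default_expand_constraints,
    expand,
    solve_equilibrium,
)

__all__ = ["IndexSeries", "SimulationResult", "run", "compute_indices"]


@dataclass
class IndexSeries:
    """Daily degradation indices plus expansion summary scalars."""

    day: np.ndarray
    beta_mean: np.ndarray
    v_r: np.ndarray
    sigma_mean: np.ndarray  # MPa
    D: np.ndarray  # mm
    D_peak_expansion: float = float("nan")
    D_post_recoil: float = float("nan")
    expansion_ratio: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.day,
                "beta_mean": self.beta_mean,
                "v_r": self.v_r,
                "sigma_mean_MPa": self.sigma_mean,
                "D_mm": self.D,
            }
        )


@dataclass
class SimulationResult:
    series: IndexSeries
    points: PointState
    mech: MechState
    expansion: ExpandResult | None


def compute_indices(
    lattice: BeamLattice, state: PointState, x_nodes: np.ndarray | None = None
) -> dict:
    """One record of the four degradation indices.

    Dead points are excluded from the molecular-weight and stress means
    but their (frozen, swollen) volume still counts toward the residual
    volume fraction only while alive; the diameter uses the crown nodes of
    the current geometry.
    """
    alive = state.alive
    V = lattice.point_volumes()
    v_r = float(np.sum(V[alive] * state.alpha_v[alive]) / V.sum())
    if alive.any():
        beta_mean = float(state.beta[alive].mean())
        m = lattice.points_per_element
        elem_alive = alive.reshape(-1, m).any(axis=1)
        sig_e = state.sigma.reshape(-1, m).max(axis=1)
        sigma_mean = float(sig_e[elem_alive].mean())
    else:
        beta_mean = float("nan")
        sigma_mean = float("nan")
    return {
        "beta_mean": beta_mean,
        "v_r": v_r,
        "sigma_mean": sigma_mean,
        "D": lattice.diameter(x_nodes),
    }


def run(
    lattice: BeamLattice | StentDesign,
    kinetics: KineticParams | None = None,
    law: mat.MaterialLaw | None = None,
    vessel: VesselSpec | None = None,
    balloon: BalloonProgram | None = None,
    waveform: Waveform | None = None,
    n_days: int = 180,
    segment_rings: int | None = 3,
    expand_first: bool = True,
    constraints: Constraints | None = None,
    solver: SolverParams | None = None,
    progress=None,
) -> SimulationResult:
    """Run expansion (optional) followed by ``n_days`` of degradation.

    ``lattice`` may be a :class:`StentDesign` (a segment of
    ``segment_rings`` rings is built) or a ready lattice.  The run is
    deterministic for a given ``kinetics.seed``.
    """
    p = kinetics or KineticParams()
    law = law or mat.MaterialLaw()
    solver = solver or SolverParams()
    if isinstance(lattice, StentDesign):
        lattice = build_lattice(lattice, segment_rings=segment_rings)

    rng = np.random.default_rng(p.seed)
    state = PointState.initial(lattice.n_points)
    mech = MechState.initial(
        lattice, E0=law.E_s0, sigma_y0=law.eta * law.sigma_y0, params=solver
    )
    m = lattice.points_per_element

    mean_bp = 0.0
    if waveform is not None:
        mean_bp = mean_pressure(waveform) * 1e-3  # kPa -> MPa

    con = constraints or _default_expand_constraints(lattice)
    expansion = None
    if expand_first and balloon is not None and vessel is not None:
        expansion = expand(
            lattice, mech, balloon, vessel,
            residual_pressure=mean_bp, constraints=con, params=solver,
        )

    has_loads = vessel is not None or mean_bp > 0.0

    def daily_equilibrium(day: int) -> None:
        if not has_loads:
            return
        try:
            solve_equilibrium(
                lattice, mech,
                LoadCase(pressure=mean_bp, vessel=vessel),
                con, solver,
            )
        except Exception as exc:
            raise RuntimeError(f"equilibrium failed at day {day}") from exc

    def refresh_properties() -> None:
        beta_eff = np.where(state.alive, state.beta, 0.0)
        E_pt = mat.modulus(beta_eff, law)
        E_pt = np.where(state.alive, E_pt, law.E_water)
        mech.E = E_pt.reshape(-1, m).mean(axis=1)
        sy_pt = mat.yield_strength(state.rate_integral, law)
        mech.sigma_y = np.maximum(sy_pt.reshape(-1, m).mean(axis=1), 1e-6)

    records = []
    daily_equilibrium(0)
    state.sigma = np.repeat(mech.stress, m)
    records.append(compute_indices(lattice, state, mech.x))

    for day in range(1, n_days + 1):
        lam = deg.degradation_rate(state.sigma, state.c_m, state.alpha_v, p)
        lam = np.where(state.alive, lam, 0.0)
        beta_before = state.beta.copy()
        state.beta = np.where(
            state.alive, deg.step_beta(state.beta, lam, p.dt), state.beta
        )
        state.rate_integral = state.rate_integral + lam * p.dt
        state.c_m = deg.diffuse_hydrolysates(lattice, state, p, p.dt, beta_before)
        _, alpha_v = deg.swelling_state(day * p.dt, p)
        state.alpha_v = np.where(state.alive, alpha_v, state.alpha_v)
        state.alive = deg.death_check(state.beta, lam, p, rng, state.alive)

        refresh_properties()
        daily_equilibrium(day)
        state.sigma = np.where(state.alive, np.repeat(mech.stress, m), state.sigma)
        records.append(compute_indices(lattice, state, mech.x))
        if progress is not None:
            progress(day)

    series = IndexSeries(
        day=np.arange(n_days + 1),
        beta_mean=np.array([r["beta_mean"] for r in records]),
        v_r=np.array([r["v_r"] for r in records]),
        sigma_mean=np.array([r["sigma_mean"] for r in records]),
        D=np.array([r["D"] for r in records]),
    )
    if expansion is not None:
        series.D_peak_expansion = expansion.D_peak
        series.D_post_recoil = expansion.D_post_recoil
        series.expansion_ratio = expansion.expansion_ratio
    return SimulationResult(series=series, points=state, mech=mech, expansion=expansion)
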