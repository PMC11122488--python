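"""Hydrolytic degradation kinetics of the stent polymer.

Each material point carries a normalized number-average molecular weight
``beta = Mn(t)/Mn(0)`` that decays by pseudo first-order scission.  The
local rate is regulated by three factors: mechanical stress (which lowers
the hydrolysis activation energy), the local concentration of acidic
hydrolysates ``C_m`` (autocatalysis), and the volume swelling ``alpha_v``
from water uptake.  Hydrolysates are produced by scission and spread along
the strut network by Fickian diffusion with a strongly
degradation-dependent diffusivity, while slowly being released to the
bloodstream.  A material point dies either when ``beta`` falls below a
threshold or by a stochastic scission event with hazard ``k*lambda``;
dead points are frozen (and keep a water-like modulus) rather than removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .geometry import BeamLattice

__all__ = [
    "KineticParams",
    "PointState",
    "degradation_rate",
    "step_beta",
    "swelling_state",
    "death_check",
    "diffuse_hydrolysates",
]

_RATE_FORMS = ("additive", "exp_all", "mixed")


@dataclass(frozen=True)
class KineticParams:
    """Degradation constants (units: mm, MPa, day).

    ``lambda0`` is the baseline hydrolysis rate of the unstressed,
    uncatalysed, unswollen polymer.  ``stress_sensitivity`` is B/(RT) of
    the Arrhenius-type stress acceleration, per MPa.  ``k`` scales the
    stochastic-scission hazard, ``beta_thre`` is the deterministic death
    threshold.  ``phi0``/``theta`` parameterize the hydrolysate diffusivity
    phi = phi0*exp(theta*(1-beta)) (phi0 given in mm^2/day).
    ``source_coeff`` converts scission (-d beta) into hydrolysate
    production, ``release_coeff`` is the first-order washout of
    hydrolysates to blood.  Swelling follows a first-order saturation
    alpha_m(t) = alpha_m_inf*(1-exp(-t/tau_sw)).
    """

    lambda0: float = 0.003  # 1/day
    stress_sensitivity: float = 0.02  # 1/MPa (gap-filling default, logged per run)
    k: float = 0.12
    beta_thre: float = 0.01
    phi0: float = 1.2e-3  # mm^2/day  (1.2e-9 m^2/day)
    theta: float = 9.43
    rho_dry: float = 1.2  # g/cm^3
    rho_water: float = 1.0  # g/cm^3
    source_coeff: float = 1.0
    release_coeff: float = 0.2  # 1/day
    alpha_m_inf: float = 0.1
    tau_sw: float = 7.0  # day
    dt: float = 1.0  # day (macro step)
    seed: int = 0
    rate_form: str = "additive"
    max_substeps: int = 200_000

    def __post_init__(self) -> None:
        for name in (
            "lambda0",
            "stress_sensitivity",
            "k",
            "beta_thre",
            "phi0",
            "theta",
            "source_coeff",
            "release_coeff",
            "alpha_m_inf",
            "tau_sw",
            "dt",
        ):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")
        if self.rate_form not in _RATE_FORMS:
            raise ValueError(f"rate_form must be one of {_RATE_FORMS}")


@dataclass
class PointState:
    """Vectorized degradation state of all material points of a lattice."""

    beta: np.ndarray  # normalized Mn, in [0, 1]
    c_m: np.ndarray  # normalized hydrolysate concentration, >= 0
    alpha_v: np.ndarray  # volume swelling factor, >= 1
    sigma: np.ndarray  # stress magnitude fed to the kinetics, MPa
    alive: np.ndarray  # bool
    rate_integral: np.ndarray  # int lambda dt, for the strength decay

    @classmethod
    def initial(cls, n_points: int) -> "PointState":
        return cls(
            beta=np.ones(n_points),
            c_m=np.zeros(n_points),
            alpha_v=np.ones(n_points),
            sigma=np.zeros(n_points),
            alive=np.ones(n_points, dtype=bool),
            rate_integral=np.zeros(n_points),
        )

    def copy(self) -> "PointState":
        return PointState(
            self.beta.copy(),
            self.c_m.copy(),
            self.alpha_v.copy(),
            self.sigma.copy(),
            self.alive.copy(),
            self.rate_integral.copy(),
        )


def degradation_rate(sigma, c_m, alpha_v, p: KineticParams):
    """Local degradation rate lambda (1/day) from the three factors.

    Default (additive) form:  lambda = lambda0*[exp(b*sigma) + C_m +
    alpha_v - 1], which reduces to lambda0 for an unstressed, uncatalysed,
    unswollen point.  Alternative parses of the same law are selectable via
    ``p.rate_form``: ``exp_all`` = lambda0*exp(b*sigma + C_m + alpha_v - 1)
    and ``mixed`` = lambda0*exp(b*sigma) + C_m + alpha_v - 1 (the latter is
    dimensionally inconsistent and provided for comparison only).
    """
    sigma = np.asarray(sigma, dtype=float)
    c_m = np.asarray(c_m, dtype=float)
    alpha_v = np.asarray(alpha_v, dtype=float)
    if np.any(c_m < 0.0):
        raise ValueError("hydrolysate concentration must be non-negative")
    if np.any(alpha_v < 1.0 - 1e-12):
        raise ValueError("alpha_v must be >= 1")
    b = p.stress_sensitivity
    s = np.abs(sigma)
    if p.rate_form == "additive":
        lam = p.lambda0 * (np.exp(b * s) + c_m + alpha_v - 1.0)
    elif p.rate_form == "exp_all":
        lam = p.lambda0 * np.exp(b * s + c_m + alpha_v - 1.0)
    else:  # mixed
        lam = p.lambda0 * np.exp(b * s) + c_m + alpha_v - 1.0
    return float(lam) if lam.ndim == 0 else lam


def step_beta(beta, lam, dt: float):
    """Advance beta over one step of length dt at frozen rate lam.

    Exact integral of d(beta)/dt = -lambda*beta: beta' = beta*exp(-lam*dt).
    """
    beta = np.asarray(beta, dtype=float)
    lam = np.asarray(lam, dtype=float)
    out = beta * np.exp(-lam * dt)
    return float(out) if out.ndim == 0 else out


def swelling_state(t: float, p: KineticParams) -> tuple[float, float]:
    """Mass and volume swelling indices at time t (days).

    alpha_m(t) = alpha_m_inf*(1 - exp(-t/tau_sw));
    alpha_v = 1 + (rho_dry/rho_water)*alpha_m.
    """
    if t < 0.0:
        raise ValueError("t must be non-negative")
    if p.tau_sw == 0.0 or p.alpha_m_inf == 0.0:
        alpha_m = p.alpha_m_inf if t > 0.0 and p.tau_sw == 0.0 else 0.0
    else:
        alpha_m = p.alpha_m_inf * -np.expm1(-t / p.tau_sw)
    alpha_v = 1.0 + (p.rho_dry / p.rho_water) * alpha_m
    return float(alpha_m), float(alpha_v)


def death_probability(lam, k: float, dt: float):
    """Per-step stochastic death probability 1 - exp(-k*lambda*dt).

    Exact integral of the scission probability density p(t) =
    k*lambda*exp(-k*lambda*t) over one step at frozen lambda.
    """
    lam = np.asarray(lam, dtype=float)
    out = -np.expm1(-k * lam * dt)
    return float(out) if out.ndim == 0 else out


def death_check(
    beta,
    lam,
    p: KineticParams,
    rng: np.random.Generator,
    alive=None,
) -> np.ndarray:
    """Apply the two death criteria; returns the updated alive mask.

    A point dies when beta < beta_thre, or when a uniform draw falls below
    the stochastic scission probability 1 - exp(-k*lambda*dt).  One
    independent draw is used per alive point per step.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    lam = np.broadcast_to(np.asarray(lam, dtype=float), beta.shape)
    alive = (
        np.ones(beta.shape, dtype=bool)
        if alive is None
        else np.atleast_1d(np.asarray(alive, dtype=bool)).copy()
    )
    idx = np.flatnonzero(alive)
    if idx.size == 0:
        return alive
    u = rng.random(idx.size)
    prob = death_probability(lam[idx], p.k, p.dt)
    dead = (beta[idx] < p.beta_thre) | (u < prob)
    alive[idx[dead]] = False
    return alive


def _diffusion_operator(
    lattice: BeamLattice, beta: np.ndarray, alive: np.ndarray, p: KineticParams
) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Symmetric conductance matrix W (mm^3/day) and point volumes (mm^3).

    Material points form a graph: a chain along each strut (conductance
    phi*A/d between neighbours, phi by harmonic mean), joined at lattice
    nodes by the exact star-mesh transform so junctions carry no spurious
    volume.  Dead points are disconnected (their state is frozen).
    """
    m = lattice.points_per_element
    L = lattice.element_lengths()
    A = lattice.width * lattice.thickness
    V = lattice.point_volumes()
    phi = p.phi0 * np.exp(p.theta * (1.0 - np.clip(beta, 0.0, 1.0)))
    phi = np.where(alive, phi, 0.0)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    # chain edges inside each element
    pts = np.arange(lattice.n_points).reshape(lattice.n_elements, m)
    if m > 1:
        d = L / m
        for s in range(m - 1):
            i = pts[:, s]
            j = pts[:, s + 1]
            pi, pj = phi[i], phi[j]
            with np.errstate(divide="ignore", invalid="ignore"):
                w = np.where(
                    (pi > 0) & (pj > 0),
                    A / (0.5 * d * (1.0 / np.where(pi > 0, pi, 1.0)
                                    + 1.0 / np.where(pj > 0, pj, 1.0))),
                    0.0,
                )
            rows.append(i)
            cols.append(j)
            vals.append(w)

    # junction edges: star-mesh transform at every lattice node
    d_half = 0.5 * L / m
    legs: dict[int, list[tuple[int, float]]] = {}
    for e in range(lattice.n_elements):
        n0, n1 = lattice.elements[e]
        p0, p1 = pts[e, 0], pts[e, -1]
        for node, pt in ((n0, p0), (n1, p1)):
            g = phi[pt] * A[e] / d_half[e] if phi[pt] > 0 else 0.0
            legs.setdefault(int(node), []).append((int(pt), g))
    for node, lg in legs.items():
        if len(lg) < 2:
            continue
        gsum = sum(g for _, g in lg)
        if gsum <= 0:
            continue
        for a in range(len(lg)):
            for b in range(a + 1, len(lg)):
                i, gi = lg[a]
                j, gj = lg[b]
                w = gi * gj / gsum
                if w > 0:
                    rows.append(np.array([i]))
                    cols.append(np.array([j]))
                    vals.append(np.array([w]))

    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        v = np.concatenate(vals)
        W = sparse.coo_matrix(
            (np.concatenate([v, v]), (np.concatenate([r, c]), np.concatenate([c, r]))),
            shape=(lattice.n_points, lattice.n_points),
        ).tocsr()
    else:
        W = sparse.csr_matrix((lattice.n_points, lattice.n_points))
    return W, V


def diffuse_hydrolysates(
    lattice: BeamLattice,
    state: PointState,
    p: KineticParams,
    dt: float,
    beta_before: np.ndarray | None = None,
) -> np.ndarray:
    """One macro-step of hydrolysate reaction-diffusion; returns new C_m.

    Integrates dC/dt = div(phi grad C) + S - k_rel*C along the strut graph
    with an explicit scheme, automatically sub-stepped to satisfy the
    stability limit.  The source S = s0*(beta_before - beta_now)/dt ties
    hydrolysate production to chain scission over the macro step; pass
    ``beta_before`` (beta at the start of the step) to enable it.
    """
    W, V = _diffusion_operator(lattice, state.beta, state.alive, p)
    C = state.c_m.astype(float).copy()
    alive = state.alive
    S = np.zeros_like(C)
    if beta_before is not None and p.source_coeff > 0.0:
        S = p.source_coeff * (np.asarray(beta_before) - state.beta) / dt
        S = np.where(alive, np.maximum(S, 0.0), 0.0)

    deg = np.asarray(W.sum(axis=1)).ravel()
    rate = np.where(alive, deg / V + p.release_coeff, 0.0)
    rmax = rate.max() if rate.size else 0.0
    if rmax > 0.0:
        n_sub = max(1, int(np.ceil(dt * rmax / 0.4)))
    else:
        n_sub = 1
    if n_sub > p.max_substeps:
        raise RuntimeError(
            f"diffusion stability requires {n_sub} sub-steps (cap {p.max_substeps}); "
            "refine the time step or the lattice"
        )
    h = dt / n_sub
    krel = np.where(alive, p.release_coeff, 0.0)
    for _ in range(n_sub):
        flux = W @ C - deg * C
        dC = flux / V + S - krel * C
        dC = np.where(alive, dC, 0.0)
        C = C + h * dC
    return np.maximum(C, 0.0)
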