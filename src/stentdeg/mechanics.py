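"""Quasi-static corotational beam-lattice solver and stent procedures.

The stent struts are modelled as corotational Euler-Bernoulli beams with
fiber-resolved rectangular cross-sections and an elastic-perfectly-plastic
axial response per fiber, using each element's *current* modulus and yield
strength (both decay as degradation proceeds).  Large rotations are
carried by nodal triads; local deformations stay small because the lattice
is finely subdivided.  Crimping presses the lattice against a shrinking
rigid cylinder (an idealization of the circumferential crimp plates) via
penalty contact; expansion applies balloon pressure against the artery
foundation.  An implicit Newton solve with adaptive load-step bisection is
used throughout, which avoids the kinetic-energy artifacts of explicit
dynamics in what is a quasi-static problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.interpolate import CubicSpline
from scipy.sparse.linalg import spsolve

from .geometry import BeamLattice
from .loading import BalloonProgram, VesselSpec, mr_tube_pressure

__all__ = [
    "SolverParams",
    "Constraints",
    "LoadCase",
    "MechState",
    "CrimpResult",
    "ExpandResult",
    "solve_equilibrium",
    "crimp",
    "expand",
    "recoil_rate",
]

_GAUSS_XI = np.array([0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0)])
_GAUSS_W = np.array([0.5, 0.5])


# --------------------------------------------------------------------------
# small batched rotation helpers
# --------------------------------------------------------------------------

def _rotvec_to_matrix(v: np.ndarray) -> np.ndarray:
    """Rodrigues formula, batched over leading axes; v shape (..., 3)."""
    theta = np.linalg.norm(v, axis=-1, keepdims=True)
    small = theta[..., 0] < 1e-8
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(theta > 0, np.sin(theta) / theta, 1.0)
        b = np.where(theta > 0, (1.0 - np.cos(theta)) / theta**2, 0.5)
    a = np.where(small[..., None], 1.0 - theta[..., 0][..., None] ** 2 / 6.0, a)
    b = np.where(small[..., None], 0.5 - theta[..., 0][..., None] ** 2 / 24.0, b)
    K = _skew(v)
    K2 = K @ K
    eye = np.broadcast_to(np.eye(3), K.shape)
    return eye + a[..., None] * K + b[..., None] * K2


def _matrix_to_rotvec(R: np.ndarray) -> np.ndarray:
    """Inverse of Rodrigues for rotations well below pi, batched."""
    s = 0.5 * np.stack(
        [
            R[..., 2, 1] - R[..., 1, 2],
            R[..., 0, 2] - R[..., 2, 0],
            R[..., 1, 0] - R[..., 0, 1],
        ],
        axis=-1,
    )
    c = 0.5 * (np.trace(R, axis1=-2, axis2=-1) - 1.0)
    sn = np.linalg.norm(s, axis=-1)
    theta = np.arctan2(sn, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(sn > 1e-12, theta / np.where(sn > 1e-12, sn, 1.0), 1.0)
    f = np.where(theta < 1e-6, 1.0 + theta**2 / 6.0, f)
    return s * f[..., None]


def _skew(v: np.ndarray) -> np.ndarray:
    out = np.zeros(v.shape[:-1] + (3, 3))
    out[..., 0, 1] = -v[..., 2]
    out[..., 0, 2] = v[..., 1]
    out[..., 1, 0] = v[..., 2]
    out[..., 1, 2] = -v[..., 0]
    out[..., 2, 0] = -v[..., 1]
    out[..., 2, 1] = v[..., 0]
    return out


def _radial_units(x: np.ndarray) -> np.ndarray:
    """In-plane radial unit vectors of nodes (stent axis along z)."""
    r = np.hypot(x[:, 0], x[:, 1])
    r = np.where(r > 1e-12, r, 1.0)
    e = np.zeros_like(x)
    e[:, 0] = x[:, 0] / r
    e[:, 1] = x[:, 1] / r
    return e


# --------------------------------------------------------------------------
# problem definition
# --------------------------------------------------------------------------

@dataclass
class SolverParams:
    tol_rel: float = 1e-8
    tol_abs: float = 1e-7  # N, force-resolution floor of the residual check
    # acceptance when Newton stagnates on a near-mechanism configuration
    # (deep plastic collapse of a buckled lattice): the better of an
    # absolute floor and a relative fraction of the load norm
    tol_stagnation: float = 1e-3  # N
    tol_stagnation_rel: float = 0.01
    max_iter: int = 150
    max_bisections: int = 8
    contact_stiffness: float = 1.0e4  # N/mm per node
    penetration_tol: float = 1e-2  # mm
    fiber_grid: tuple[int, int] = (4, 4)  # across width, thickness


class Constraints:
    """Per-node kinematic constraints in an optionally rotated basis.

    Each node owns a 3x3 orthonormal basis Q (columns = admissible
    directions); the fixed mask selects which of the 6 basis components
    (3 translations, 3 rotations) are held at zero.
    """

    def __init__(self, n_nodes: int):
        self.Q = np.tile(np.eye(3), (n_nodes, 1, 1))
        self.fixed = np.zeros((n_nodes, 6), dtype=bool)

    @classmethod
    def radial_only(cls, lattice: BeamLattice, nodes: np.ndarray) -> "Constraints":
        """Allow only radial translation for the given nodes (rotations free).

        This mirrors the boundary condition that permits purely radial
        stent deformation at selected crowns.
        """
        con = cls(lattice.n_nodes)
        e_r = _radial_units(lattice.nodes)
        for n in np.atleast_1d(nodes):
            er = e_r[n]
            ez = np.array([0.0, 0.0, 1.0])
            et = np.cross(ez, er)
            con.Q[n] = np.column_stack([er, et, ez])
            con.fixed[n, 1] = True  # tangential
            con.fixed[n, 2] = True  # axial
        return con

    def fix_all(self, nodes) -> "Constraints":
        self.fixed[np.atleast_1d(nodes), :] = True
        return self

    def fix(self, nodes, dofs) -> "Constraints":
        for d in np.atleast_1d(dofs):
            self.fixed[np.atleast_1d(nodes), d] = True
        return self


@dataclass
class LoadCase:
    """External loads: dead nodal forces, outward radial pressure (MPa),
    a rigid crimp cylinder (penalty contact at ``contact_radius``), and the
    artery foundation (inward Mooney-Rivlin tube pressure once the stent
    exceeds the vessel's unloaded lumen)."""

    point_forces: np.ndarray | None = None  # (N, 3), N
    pressure: float = 0.0  # MPa, outward on strut inner faces
    contact_radius: float | None = None  # mm
    vessel: VesselSpec | None = None
    # automatic stabilization: weak springs to an anchor configuration,
    # used while tracking snap-through during crimping (zero = off)
    spring_k: float = 0.0  # N/mm per node
    spring_anchor: np.ndarray | None = None  # (N, 3)

    def foundation_spline(self) -> CubicSpline:
        spl = _foundation_cache.get(self.vessel)
        if spl is None:
            lam = np.linspace(1.0, 1.6, 121)
            p = np.array([mr_tube_pressure(l, self.vessel) for l in lam])
            spl = CubicSpline(lam, p)
            _foundation_cache[self.vessel] = spl
        return spl


_foundation_cache: dict[VesselSpec, CubicSpline] = {}


@dataclass
class MechState:
    """Mechanical state: node positions, nodal triads, committed plastic
    strains per element/Gauss point/fiber, and current per-element modulus
    and yield strength."""

    x: np.ndarray  # (N, 3)
    R: np.ndarray  # (N, 3, 3)
    eps_p: np.ndarray  # (E, 2, nf)
    E: np.ndarray  # (E,) MPa
    sigma_y: np.ndarray  # (E,) MPa
    stress: np.ndarray  # (E,) MPa, max |fiber stress| at last equilibrium

    @classmethod
    def initial(
        cls, lattice: BeamLattice, E0: float = 3000.0, sigma_y0: float = 49.5,
        params: SolverParams | None = None,
    ) -> "MechState":
        nf = int(np.prod((params or SolverParams()).fiber_grid))
        ne = lattice.n_elements
        return cls(
            x=lattice.nodes.copy(),
            R=np.tile(np.eye(3), (lattice.n_nodes, 1, 1)),
            eps_p=np.zeros((ne, 2, nf)),
            E=np.full(ne, float(E0)),
            sigma_y=np.full(ne, float(sigma_y0)),
            stress=np.zeros(ne),
        )

    def copy(self) -> "MechState":
        return MechState(
            self.x.copy(), self.R.copy(), self.eps_p.copy(),
            self.E.copy(), self.sigma_y.copy(), self.stress.copy(),
        )


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, diagnostics: dict | None = None):
        super().__init__(msg)
        self.diagnostics = diagnostics or {}


# --------------------------------------------------------------------------
# element precomputation
# --------------------------------------------------------------------------

class _Model:
    """Precomputed element data for one lattice + fiber discretization."""

    def __init__(self, lattice: BeamLattice, params: SolverParams):
        self.lattice = lattice
        self.params = params
        x0 = lattice.nodes
        self.n1 = lattice.elements[:, 0]
        self.n2 = lattice.elements[:, 1]
        d = x0[self.n2] - x0[self.n1]
        self.L0 = np.linalg.norm(d, axis=1)
        t0 = d / self.L0[:, None]

        # initial frames: local z along the (roughly radial) thickness
        # direction, local y circumferential
        mid = 0.5 * (x0[self.n1] + x0[self.n2])
        ref = np.zeros_like(mid)
        ref[:, 0] = mid[:, 0]
        ref[:, 1] = mid[:, 1]
        nrm = np.linalg.norm(ref, axis=1)
        bad = (nrm < 1e-8) | (np.abs(np.einsum("ij,ij->i", ref, t0)) > 0.99 * nrm)
        for e in np.flatnonzero(bad):
            k = np.argmin(np.abs(t0[e]))
            ref[e] = np.eye(3)[k]
        z0 = ref - np.einsum("ij,ij->i", ref, t0)[:, None] * t0
        z0 /= np.linalg.norm(z0, axis=1)[:, None]
        y0 = np.cross(z0, t0)
        self.R0 = np.stack([t0, y0, z0], axis=-1)  # columns (t, y, z)

        # fiber grid over the rectangle (y across width, z across thickness);
        # Gauss-Legendre stations so area and inertia integrate exactly
        nw, nt = params.fiber_grid
        gy, wy = np.polynomial.legendre.leggauss(nw)
        gz, wz = np.polynomial.legendre.leggauss(nt)
        YY, ZZ = np.meshgrid(0.5 * gy, 0.5 * gz, indexing="ij")
        WW = np.outer(0.5 * wy, 0.5 * wz)
        w = lattice.width[:, None]
        t = lattice.thickness[:, None]
        self.fy = w * YY.ravel()[None, :]  # (E, nf)
        self.fz = t * ZZ.ravel()[None, :]
        self.fA = (lattice.width * lattice.thickness)[:, None] * WW.ravel()[None, :]
        self.nf = nw * nt

        # torsion constant of a rectangle (a >= b)
        a = np.maximum(lattice.width, lattice.thickness)
        b = np.minimum(lattice.width, lattice.thickness)
        self.J = a * b**3 * (1.0 / 3.0 - 0.21 * (b / a) * (1.0 - b**4 / (12.0 * a**4)))

        # curvature shape-function values at the Gauss points
        self.g1 = (6.0 * _GAUSS_XI - 4.0)[None, :] / self.L0[:, None]  # (E, 2)
        self.g2 = (6.0 * _GAUSS_XI - 2.0)[None, :] / self.L0[:, None]

        # tributary outer-surface areas for pressure loading
        areas = np.zeros(lattice.n_nodes)
        half = 0.5 * self.L0 * lattice.width
        np.add.at(areas, self.n1, half)
        np.add.at(areas, self.n2, half)
        self.trib_area = areas

        # DOF scatter indices
        ne = lattice.n_elements
        edof = np.empty((ne, 12), dtype=np.intp)
        for i, n in enumerate((self.n1, self.n2)):
            edof[:, 6 * i : 6 * i + 3] = 6 * n[:, None] + np.arange(3)
            edof[:, 6 * i + 3 : 6 * i + 6] = 6 * n[:, None] + 3 + np.arange(3)
        self.edof = edof
        self.rows = np.repeat(edof, 12, axis=1).ravel()
        self.cols = np.tile(edof, (1, 12)).ravel()

    # -- core: internal force, tangent, stresses -----------------------
    def internal(self, state: MechState, nu: float = 0.3):
        x, R = state.x, state.R
        n1, n2 = self.n1, self.n2
        d = x[n2] - x[n1]
        L = np.linalg.norm(d, axis=1)
        t = d / L[:, None]

        zref = np.einsum("eij,ej->ei", 0.5 * (R[n1] + R[n2]), self.R0[:, :, 2])
        z = zref - np.einsum("ej,ej->e", zref, t)[:, None] * t
        z /= np.linalg.norm(z, axis=1)[:, None]
        y = np.cross(z, t)
        Rcr = np.stack([t, y, z], axis=-1)

        Rb1 = np.einsum("eji,ejk,ekl->eil", Rcr, R[n1], self.R0)
        Rb2 = np.einsum("eji,ejk,ekl->eil", Rcr, R[n2], self.R0)
        th1 = _matrix_to_rotvec(Rb1)  # (E, 3) local end rotations
        th2 = _matrix_to_rotvec(Rb2)
        ubar = (L * L - self.L0 * self.L0) / (L + self.L0)

        Ee = state.E[:, None]
        sy = state.sigma_y[:, None]
        G = state.E / (2.0 * (1.0 + nu))
        GJ = G * self.J

        f_l = np.zeros((len(L), 7))
        k_l = np.zeros((len(L), 7, 7))
        new_eps = np.empty_like(state.eps_p)
        smax = np.zeros(len(L))

        eps_a = (ubar / self.L0)[:, None]
        for g in range(2):
            c_y = self.g1[:, g] * th1[:, 1] + self.g2[:, g] * th2[:, 1]
            c_z = self.g1[:, g] * th1[:, 2] + self.g2[:, g] * th2[:, 2]
            eps = eps_a + self.fz * c_y[:, None] - self.fy * c_z[:, None]
            s_tr = Ee * (eps - state.eps_p[:, g, :])
            yielded = np.abs(s_tr) > sy
            s = np.clip(s_tr, -sy, sy)
            new_eps[:, g, :] = np.where(yielded, eps - s / Ee, state.eps_p[:, g, :])
            # perfectly plastic response; a tiny hardening in the *tangent*
            # only keeps the Newton matrix non-singular when a whole
            # section yields (the residual stays exactly perfectly plastic)
            Et = np.where(yielded, 1e-4 * Ee, Ee * np.ones_like(s))
            smax = np.maximum(smax, np.abs(s).max(axis=1))

            N = np.einsum("ef,ef->e", s, self.fA)
            My = np.einsum("ef,ef->e", s * self.fz, self.fA)
            Mz = -np.einsum("ef,ef->e", s * self.fy, self.fA)
            w = _GAUSS_W[g] * self.L0
            f_l[:, 0] += w * N / self.L0
            f_l[:, 2] += w * self.g1[:, g] * My
            f_l[:, 3] += w * self.g1[:, g] * Mz
            f_l[:, 5] += w * self.g2[:, g] * My
            f_l[:, 6] += w * self.g2[:, g] * Mz

            # strain-DOF matrix a (E, nf, 7)
            a = np.zeros((len(L), self.nf, 7))
            a[:, :, 0] = 1.0 / self.L0[:, None]
            a[:, :, 2] = self.fz * self.g1[:, g][:, None]
            a[:, :, 3] = -self.fy * self.g1[:, g][:, None]
            a[:, :, 5] = self.fz * self.g2[:, g][:, None]
            a[:, :, 6] = -self.fy * self.g2[:, g][:, None]
            k_l += w[:, None, None] * np.einsum(
                "efi,ef,efj->eij", a, Et * self.fA, a
            )

        tau = th2[:, 0] - th1[:, 0]
        Mt = GJ * tau / self.L0
        f_l[:, 1] = -Mt
        f_l[:, 4] = Mt
        kt = GJ / self.L0
        k_l[:, 1, 1] += kt
        k_l[:, 4, 4] += kt
        k_l[:, 1, 4] -= kt
        k_l[:, 4, 1] -= kt

        # corotational projector B (E, 7, 12)
        ne = len(L)
        B = np.zeros((ne, 7, 12))
        B[:, 0, 0:3] = -t
        B[:, 0, 6:9] = t
        S = _skew(t) / L[:, None, None]
        RcrT = np.transpose(Rcr, (0, 2, 1))
        P = np.broadcast_to(np.eye(3), (ne, 3, 3)) - 0.5 * t[:, :, None] * t[:, None, :]
        H = 0.5 * t[:, :, None] * t[:, None, :]
        B[:, 1:4, 0:3] = RcrT @ S
        B[:, 1:4, 3:6] = RcrT @ P
        B[:, 1:4, 6:9] = -RcrT @ S
        B[:, 1:4, 9:12] = -RcrT @ H
        B[:, 4:7, 0:3] = RcrT @ S
        B[:, 4:7, 3:6] = -RcrT @ H
        B[:, 4:7, 6:9] = -RcrT @ S
        B[:, 4:7, 9:12] = RcrT @ P

        f_e = np.einsum("eij,ei->ej", B, f_l)
        k_e = np.einsum("eij,eik,ekl->ejl", B, k_l, B)

        # geometric (string) stiffness from the axial force
        Ng = f_l[:, 0]
        Kg = (Ng / L)[:, None, None] * (
            np.broadcast_to(np.eye(3), (ne, 3, 3)) - t[:, :, None] * t[:, None, :]
        )
        for (ia, ib, sgn) in ((0, 0, 1.0), (0, 6, -1.0), (6, 0, -1.0), (6, 6, 1.0)):
            k_e[:, ia : ia + 3, ib : ib + 3] += sgn * Kg

        # assemble
        nd = 6 * self.lattice.n_nodes
        f_int = np.zeros(nd)
        np.add.at(f_int, self.edof.ravel(), f_e.ravel())
        K = sparse.coo_matrix(
            (k_e.ravel(), (self.rows, self.cols)), shape=(nd, nd)
        ).tocsr()
        return f_int, K, new_eps, smax

    # -- external loads ------------------------------------------------
    def external(self, state: MechState, load: LoadCase):
        nd = 6 * self.lattice.n_nodes
        f = np.zeros(nd)
        diagK = np.zeros((self.lattice.n_nodes, 3, 3))
        e_r = _radial_units(state.x)
        r = np.hypot(state.x[:, 0], state.x[:, 1])

        if load.point_forces is not None:
            f.reshape(-1, 6)[:, :3] += load.point_forces
        if load.pressure != 0.0:
            f.reshape(-1, 6)[:, :3] += (
                load.pressure * self.trib_area[:, None] * e_r
            )
        max_pen = 0.0
        if load.contact_radius is not None:
            g = r - load.contact_radius
            act = g > 0.0
            kp = self.params.contact_stiffness
            max_pen = float(g[act].max()) if act.any() else 0.0
            f.reshape(-1, 6)[:, :3] -= np.where(act, kp * g, 0.0)[:, None] * e_r
            diagK += (
                np.where(act, kp, 0.0)[:, None, None]
                * e_r[:, :, None]
                * e_r[:, None, :]
            )
        if load.spring_k > 0.0 and load.spring_anchor is not None:
            f.reshape(-1, 6)[:, :3] -= load.spring_k * (state.x - load.spring_anchor)
            diagK += load.spring_k * np.broadcast_to(
                np.eye(3), (self.lattice.n_nodes, 3, 3)
            )
        if load.vessel is not None:
            a0 = load.vessel.inner_radius
            spl = load.foundation_spline()
            lam = r / a0
            act = lam > 1.0
            if act.any():
                P = np.where(act, spl(np.clip(lam, 1.0, spl.x[-1])), 0.0)
                dP = np.where(act, spl(np.clip(lam, 1.0, spl.x[-1]), 1) / a0, 0.0)
                f.reshape(-1, 6)[:, :3] -= (P * self.trib_area)[:, None] * e_r
                diagK += (
                    (dP * self.trib_area)[:, None, None]
                    * e_r[:, :, None]
                    * e_r[:, None, :]
                )
        return f, diagK, max_pen


# --------------------------------------------------------------------------
# Newton solve
# --------------------------------------------------------------------------

_model_cache: dict[int, _Model] = {}


def _get_model(lattice: BeamLattice, params: SolverParams) -> _Model:
    key = id(lattice)
    m = _model_cache.get(key)
    if m is None or m.params.fiber_grid != params.fiber_grid:
        m = _Model(lattice, params)
        _model_cache[key] = m
    m.params = params
    return m


def _constraint_transform(con: Constraints) -> tuple[sparse.csr_matrix, np.ndarray]:
    n = len(con.Q)
    blocks = []
    for i in range(n):
        Q6 = np.zeros((6, 6))
        Q6[:3, :3] = con.Q[i]
        Q6[3:, 3:] = con.Q[i]
        blocks.append(Q6)
    T = sparse.block_diag(blocks, format="csr")
    free = ~con.fixed.ravel()
    return T, free


def solve_equilibrium(
    lattice: BeamLattice,
    state: MechState,
    load: LoadCase,
    constraints: Constraints,
    params: SolverParams | None = None,
) -> dict:
    """Find static equilibrium; mutates ``state`` (positions, triads,
    committed plastic strains, element stresses).

    Returns a diagnostics dict with the converged residual and iteration
    count.  Raises :class:`ConvergenceError` if Newton fails.
    """
    params = params or SolverParams()
    model = _get_model(lattice, params)
    T, free = _constraint_transform(constraints)
    nd = 6 * lattice.n_nodes

    res_prev = None
    ratio_hist: list[float] = []
    last_step = None  # (scaled du, dw) for backtracking
    best_res = np.inf
    stall = 0
    for it in range(params.max_iter):
        f_int, K, new_eps, smax = model.internal(state)
        f_ext, diagK, max_pen = model.external(state, load)
        r = f_ext - f_int
        r_red = (T.T @ r)[free]
        ref = max(float(np.linalg.norm((T.T @ f_ext)[free])), params.tol_abs)
        res = float(np.linalg.norm(r_red))
        if (
            last_step is not None
            and res_prev is not None
            and res > 4.0 * res_prev
        ):
            # the last (possibly boosted) update overshot: backtrack half
            du_b, dw_b = last_step
            state.x = state.x - 0.5 * du_b
            state.R = _rotvec_to_matrix(-0.5 * dw_b) @ state.R
            last_step = (0.5 * du_b, 0.5 * dw_b)
            ratio_hist.clear()
            continue
        stagnated = stall >= 30 and res <= max(
            params.tol_stagnation, params.tol_stagnation_rel * ref
        )
        if res <= params.tol_rel * ref + params.tol_abs or stagnated:
            state.eps_p = new_eps
            state.stress = smax
            if max_pen > params.penetration_tol:
                raise ConvergenceError(
                    f"contact penetration {max_pen:.3g} mm exceeds tolerance",
                    {"penetration": max_pen},
                )
            return {
                "iterations": it,
                "residual": res,
                "penetration": max_pen,
                "stagnated": stagnated,
            }
        if res < 0.995 * best_res:
            best_res = res
            stall = 0
        else:
            stall += 1

        # stabilizing load stiffness (contact + foundation)
        idx = np.arange(lattice.n_nodes)
        Kl = sparse.coo_matrix(
            (
                diagK.ravel(),
                (
                    np.repeat(6 * idx[:, None] + np.arange(3), 3, axis=1).ravel(),
                    np.tile(6 * idx[:, None] + np.arange(3), (1, 3)).ravel(),
                ),
            ),
            shape=(nd, nd),
        ).tocsr()
        Kt = T.T @ (K + Kl) @ T
        Kff = Kt[free][:, free].tocsc()
        try:
            dq = spsolve(Kff, r_red)
        except Exception as exc:  # singular system
            raise ConvergenceError(f"linear solve failed: {exc}") from exc
        if not np.all(np.isfinite(dq)):
            raise ConvergenceError("non-finite Newton increment")
        dq_full = np.zeros(nd)
        dq_full[free] = dq
        dq_full = T @ dq_full
        du = dq_full.reshape(-1, 6)[:, :3]
        dw = dq_full.reshape(-1, 6)[:, 3:]

        # the elastic tangent over-stiffens plastified sections, giving
        # steady linear convergence; an Aitken-style boost of the increment
        # restores near-quadratic progress once the ratio settles
        boost = 1.0
        if res_prev is not None and res_prev > 0:
            ratio = res / res_prev
            ratio_hist.append(ratio)
            recent = ratio_hist[-3:]
            if len(recent) == 3 and all(0.3 < q < 0.995 for q in recent):
                rho = recent[-1]
                boost = min(20.0, 1.0 / (1.0 - rho))
        res_prev = res

        # trust-region style cap on translation and rotation increments
        step_u = boost * np.abs(du).max()
        step_w = boost * np.linalg.norm(dw, axis=1).max()
        scale = boost * min(1.0, 0.2 / max(step_u, 1e-30), 0.2 / max(step_w, 1e-30))
        last_step = (scale * du, scale * dw)
        state.x = state.x + scale * du
        state.R = _rotvec_to_matrix(scale * dw) @ state.R

    raise ConvergenceError(
        f"Newton failed to converge in {params.max_iter} iterations "
        f"(residual {res:.3g}, load norm {ref:.3g})",
        {"residual": res, "load_norm": ref},
    )


def _solve_stepped(
    lattice: BeamLattice,
    state: MechState,
    make_load,
    s_from: float,
    s_to: float,
    constraints: Constraints,
    params: SolverParams,
    depth: int = 0,
) -> None:
    """Advance the load parameter from s_from to s_to, bisecting on failure."""
    saved = state.copy()
    try:
        solve_equilibrium(lattice, state, make_load(s_to), constraints, params)
    except ConvergenceError:
        if depth >= params.max_bisections:
            raise
        state.x, state.R, state.eps_p = saved.x, saved.R, saved.eps_p
        state.stress = saved.stress
        mid = 0.5 * (s_from + s_to)
        _solve_stepped(lattice, state, make_load, s_from, mid, constraints, params, depth + 1)
        _solve_stepped(lattice, state, make_load, mid, s_to, constraints, params, depth + 1)


# --------------------------------------------------------------------------
# procedures
# --------------------------------------------------------------------------

@dataclass
class CrimpResult:
    curve: np.ndarray  # (n, 2): diameter mm, total radial force N
    D_crimp: float
    D_recoil: float
    radial_stiffness: float  # N/mm
    recoil_rate: float  # %


@dataclass
class ExpandResult:
    D_peak: float
    D_post_recoil: float
    expansion_ratio: float


def recoil_rate(D_crimp: float, D_recoil: float) -> float:
    """Elastic recoil after crimping, percent: |D_crimp - D_recoil| / D_crimp * 100."""
    if D_crimp <= 0.0:
        raise ValueError("D_crimp must be positive")
    return round(abs(D_crimp - D_recoil) / D_crimp * 100.0, 2)


def _default_crimp_constraints(lattice: BeamLattice) -> Constraints:
    """Radial-only motion for the crown nodes of the first ring."""
    z = lattice.nodes[lattice.crown_nodes, 2]
    first = lattice.crown_nodes[z <= z.min() + 1e-9]
    return Constraints.radial_only(lattice, first)


def crimp(
    lattice: BeamLattice,
    state: MechState,
    target_diameter: float = 1.4,
    n_steps: int = 40,
    release_steps: int = 20,
    elastic_window: float = 0.1,
    stabilization: float = 0.05,
    constraints: Constraints | None = None,
    params: SolverParams | None = None,
) -> CrimpResult:
    """Crimp the stent against a shrinking rigid cylinder, then release.

    Returns the force-diameter curve during compression, the diameters at
    maximal crimp and after recoil, the radial stiffness (least-squares
    slope of the initial elastic stage of the curve) and the recoil rate.
    """
    params = params or SolverParams()
    D0 = lattice.diameter(state.x)
    if target_diameter >= D0:
        raise ValueError("target diameter must be below the initial diameter")
    con = constraints or _default_crimp_constraints(lattice)
    model = _get_model(lattice, params)

    r_max = float(np.hypot(state.x[:, 0], state.x[:, 1]).max()) + 1e-6
    r_target = target_diameter / 2.0
    anchor = state.x.copy()

    def make_load(s: float) -> LoadCase:
        return LoadCase(
            contact_radius=r_max + (r_target - r_max) * s,
            spring_k=stabilization, spring_anchor=anchor,
        )

    curve = []
    s_prev = 0.0
    for s in np.linspace(1.0 / n_steps, 1.0, n_steps):
        anchor = state.x.copy()
        _solve_stepped(lattice, state, make_load, s_prev, s, con, params)
        s_prev = s
        rc = r_max + (r_target - r_max) * s
        r = np.hypot(state.x[:, 0], state.x[:, 1])
        force = params.contact_stiffness * np.clip(r - rc, 0.0, None).sum()
        curve.append((lattice.diameter(state.x), force))
    D_crimp = lattice.diameter(state.x)

    def make_release(s: float) -> LoadCase:
        return LoadCase(
            contact_radius=r_target + (r_max - r_target) * s,
            spring_k=stabilization, spring_anchor=anchor,
        )

    s_prev = 0.0
    for s in np.linspace(1.0 / release_steps, 1.0, release_steps):
        anchor = state.x.copy()
        _solve_stepped(lattice, state, make_release, s_prev, s, con, params)
        s_prev = s
    solve_equilibrium(lattice, state, LoadCase(), con, params)
    D_recoil = lattice.diameter(state.x)

    curve = np.array(curve)
    # stiffness: initial elastic stage, configurable fraction of the travel
    travel = D0 - target_diameter
    lo = D0 - elastic_window * travel
    m = (curve[:, 0] >= lo) & (curve[:, 1] > 0.0)
    if m.sum() >= 2:
        A = np.column_stack([curve[m, 0], np.ones(m.sum())])
        slope, _ = np.linalg.lstsq(A, curve[m, 1], rcond=None)[0]
        stiffness = abs(float(slope))
    else:
        stiffness = float("nan")
    return CrimpResult(
        curve=curve,
        D_crimp=D_crimp,
        D_recoil=D_recoil,
        radial_stiffness=stiffness,
        recoil_rate=recoil_rate(D_crimp, D_recoil),
    )


def _default_expand_constraints(lattice: BeamLattice) -> Constraints:
    """Radial-only motion for a few crowns of the middle ring."""
    z = lattice.nodes[lattice.crown_nodes, 2]
    zm = np.median(lattice.nodes[:, 2])
    order = np.argsort(np.abs(z - zm))
    picked = lattice.crown_nodes[order[:6]]
    return Constraints.radial_only(lattice, picked)


def expand(
    lattice: BeamLattice,
    state: MechState,
    balloon: BalloonProgram,
    vessel: VesselSpec,
    residual_pressure: float = 0.0,
    n_steps: int = 25,
    stabilization: float = 0.02,
    constraints: Constraints | None = None,
    params: SolverParams | None = None,
) -> ExpandResult:
    """Balloon-expand the stent against the artery foundation.

    The trapezoidal balloon history is traversed quasi-statically: pressure
    ramps to the peak (peak diameter recorded), then back down to the
    residual (e.g. mean blood) pressure; the post-recoil diameter is the
    equilibrium under vessel recoil alone.  The expansion ratio is the
    post-recoil diameter over the vessel's unloaded lumen diameter.
    """
    params = params or SolverParams()
    con = constraints or _default_expand_constraints(lattice)
    anchor = state.x.copy()

    def make_load(p: float) -> LoadCase:
        return LoadCase(pressure=p, vessel=vessel,
                        spring_k=stabilization, spring_anchor=anchor)

    p_prev = 0.0
    for p in np.linspace(balloon.peak_pressure / n_steps, balloon.peak_pressure, n_steps):
        anchor = state.x.copy()
        _solve_stepped(lattice, state, make_load, p_prev, p, con, params)
        p_prev = p
    D_peak = lattice.diameter(state.x)

    for p in np.linspace(balloon.peak_pressure, residual_pressure, n_steps)[1:]:
        anchor = state.x.copy()
        _solve_stepped(lattice, state, make_load, p_prev, p, con, params)
        p_prev = p
    # settle without stabilization under the residual pressure alone
    solve_equilibrium(
        lattice, state, LoadCase(pressure=residual_pressure, vessel=vessel), con, params
    )
    D_post = lattice.diameter(state.x)
    ratio = round(D_post / vessel.inner_diameter, 2)
    return ExpandResult(D_peak=D_peak, D_post_recoil=D_post, expansion_ratio=ratio)
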