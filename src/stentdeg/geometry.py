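"""Parametric beam lattices for bioresorbable stent designs.

A stent is idealized as a lattice of slender rectangular-section struts:
sinusoidal (zig-zag) supporting rings wrapped on a cylinder, linked by
connecting struts.  Four built-in designs mirror commercial devices
(Absorb, DESolve, Igaki-Tamai, Fantom): Absorb and DESolve share their
ring geometry and differ only in the number of connectors (3 vs 6);
Igaki-Tamai and Fantom share their ring geometry and differ only in the
connector style (straight vs wavy).

Minimal "toy" lattices with known analytic behaviour (a single beam, a
closed circular ring, a cubic grid) are provided for verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "StentDesign",
    "BeamLattice",
    "BUILTIN_DESIGNS",
    "builtin_design",
    "build_lattice",
    "toy_lattice",
]

# fraction of the angular crown pitch used as the lateral amplitude of a
# wavy connector (single-period sinusoid)
_WAVY_AMPLITUDE_FRACTION = 0.15


@dataclass(frozen=True)
class StentDesign:
    """Parametric description of one stent family.

    Lengths in mm, strut section in micrometres, amplitude ``h`` (the
    radial-ring peak-to-peak axial amplitude) in mm.
    """

    name: str
    length: float  # mm
    strut_width: float  # um
    strut_thickness: float  # um
    n_rings: int
    n_connectors: int
    crowns_per_ring: int = 6
    ring_amplitude: float | None = None  # mm; None -> 0.8 * axial ring pitch
    connector_style: str = "straight"  # straight | wavy | peak-to-valley
    nominal_outer_diameter: float = 3.0  # mm

    def __post_init__(self) -> None:
        if min(self.length, self.strut_width, self.strut_thickness) <= 0.0:
            raise ValueError("lengths and section dimensions must be positive")
        if min(self.n_rings, self.n_connectors, self.crowns_per_ring) <= 0:
            raise ValueError("counts must be positive")
        if self.n_connectors > self.crowns_per_ring:
            raise ValueError("n_connectors cannot exceed crowns_per_ring")
        if self.connector_style not in ("straight", "wavy", "peak-to-valley"):
            raise ValueError("unknown connector_style %r" % self.connector_style)

    @property
    def pitch(self) -> float:
        """Axial ring pitch, mm."""
        return self.length / self.n_rings

    @property
    def amplitude(self) -> float:
        """Resolved ring amplitude h, mm."""
        return self.ring_amplitude if self.ring_amplitude is not None else 0.8 * self.pitch

    @property
    def section_mm(self) -> tuple[float, float]:
        """(width, thickness) in mm."""
        return self.strut_width * 1e-3, self.strut_thickness * 1e-3


BUILTIN_DESIGNS: dict[str, StentDesign] = {
    "Absorb": StentDesign("Absorb", 10.5, 200.0, 150.0, 11, 3),
    "DESolve": StentDesign("DESolve", 10.5, 200.0, 150.0, 11, 6),
    "Igaki-Tamai": StentDesign("Igaki-Tamai", 10.0, 200.0, 170.0, 6, 3),
    "Fantom": StentDesign("Fantom", 10.0, 200.0, 170.0, 6, 3, connector_style="wavy"),
}


def builtin_design(name: str) -> StentDesign:
    """Return one of the four built-in commercial stent designs."""
    try:
        return BUILTIN_DESIGNS[name]
    except KeyError:
        raise ValueError(
            "unknown design %r; valid names: %s" % (name, ", ".join(sorted(BUILTIN_DESIGNS)))
        ) from None


@dataclass
class BeamLattice:
    """Nodes, beam elements and attached material points of one stent.

    Node positions are stored Cartesian (mm) with the stent axis along z;
    ``nodes_cylindrical`` exposes (r, theta, z).  Each element carries its
    rectangular section (width, thickness in mm) and a role tag ("ring" or
    "connector").  ``points_per_element`` equally spaced material points
    (the degradation state carriers) are attached to every element; each
    owns an equal share of its element volume.
    """

    nodes: np.ndarray  # (N, 3) float, Cartesian mm
    elements: np.ndarray  # (E, 2) int
    width: np.ndarray  # (E,) mm
    thickness: np.ndarray  # (E,) mm
    role: np.ndarray  # (E,) str
    points_per_element: int = 4
    crown_nodes: np.ndarray | None = None  # indices used for diameter readout

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.intp)
        self.width = np.asarray(self.width, dtype=float)
        self.thickness = np.asarray(self.thickness, dtype=float)
        self.role = np.asarray(self.role)
        if self.crown_nodes is None:
            self.crown_nodes = np.arange(len(self.nodes))
        else:
            self.crown_nodes = np.asarray(self.crown_nodes, dtype=np.intp)
        if self.n_components != 1:
            raise ValueError("lattice must be a single connected component")

    # -- basic sizes ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_points(self) -> int:
        return self.n_elements * self.points_per_element

    @property
    def n_components(self) -> int:
        i, j = self.elements.T
        adj = coo_matrix(
            (np.ones(len(i)), (i, j)), shape=(self.n_nodes, self.n_nodes)
        )
        ncomp, _ = connected_components(adj, directed=False)
        return ncomp

    # -- derived geometry ----------------------------------------------
    def element_lengths(self, nodes: np.ndarray | None = None) -> np.ndarray:
        x = self.nodes if nodes is None else nodes
        d = x[self.elements[:, 1]] - x[self.elements[:, 0]]
        return np.linalg.norm(d, axis=1)

    def element_volumes(self) -> np.ndarray:
        return self.element_lengths() * self.width * self.thickness

    @property
    def point_element(self) -> np.ndarray:
        """Element index owning each material point, shape (n_points,)."""
        return np.repeat(np.arange(self.n_elements), self.points_per_element)

    def point_volumes(self) -> np.ndarray:
        return np.repeat(
            self.element_volumes() / self.points_per_element, self.points_per_element
        )

    def point_positions(self, nodes: np.ndarray | None = None) -> np.ndarray:
        """Material-point positions at fractions (i+1/2)/m along each element."""
        x = self.nodes if nodes is None else nodes
        m = self.points_per_element
        s = (np.arange(m) + 0.5) / m
        a = x[self.elements[:, 0]]
        b = x[self.elements[:, 1]]
        pts = a[:, None, :] * (1.0 - s)[None, :, None] + b[:, None, :] * s[None, :, None]
        return pts.reshape(-1, 3)

    def nodes_cylindrical(self) -> np.ndarray:
        """(r, theta in [0, 2pi), z) per node."""
        x, y, z = self.nodes.T
        r = np.hypot(x, y)
        th = np.mod(np.arctan2(y, x), 2.0 * np.pi)
        return np.column_stack([r, th, z])

    def diameter(self, nodes: np.ndarray | None = None) -> float:
        """Stent diameter: twice the mean radius of the crown nodes."""
        x = self.nodes if nodes is None else nodes
        r = np.hypot(x[self.crown_nodes, 0], x[self.crown_nodes, 1])
        return 2.0 * float(np.mean(r))


def build_lattice(
    design: StentDesign,
    segment_rings: int | None = None,
    subdivisions: int = 3,
    points_per_element: int = 4,
) -> BeamLattice:
    """Build the beam lattice of a stent design.

    ``segment_rings`` limits the model to the first N rings (the standard
    degradation fixture uses 3); ``None`` builds the full device.
    ``subdivisions`` is the number of beam elements per ring half-wave and
    per connector.
    """
    n_rings = design.n_rings if segment_rings is None else int(segment_rings)
    if n_rings < 1 or n_rings > design.n_rings:
        raise ValueError("segment_rings must be in [1, n_rings]")
    c = design.crowns_per_ring
    if c < 2:
        raise ValueError("degenerate design: need at least 2 crowns per ring")
    R = design.nominal_outer_diameter / 2.0
    h = design.amplitude
    pitch = design.pitch
    if h >= pitch and n_rings > 1:
        raise ValueError("ring amplitude must be smaller than the axial pitch")
    w_mm, t_mm = design.section_mm
    nsub = int(subdivisions)
    ring_n = 2 * c * nsub  # nodes per ring

    nodes: list[np.ndarray] = []
    elems: list[tuple[int, int]] = []
    roles: list[str] = []
    crown: list[int] = []

    theta = 2.0 * np.pi * np.arange(ring_n) / ring_n
    ring_start = []
    for j in range(n_rings):
        zc = (j + 0.5) * pitch
        # alternate-phase rings so every peak faces a valley of the next ring
        z = zc + 0.5 * h * np.cos(c * theta - j * np.pi)
        start = sum(len(n) for n in nodes) if nodes else 0
        ring_start.append(start)
        ring_xyz = np.column_stack([R * np.cos(theta), R * np.sin(theta), z])
        nodes.append(ring_xyz)
        for k in range(ring_n):
            elems.append((start + k, start + (k + 1) % ring_n))
            roles.append("ring")
        crown.extend(start + np.arange(0, ring_n, nsub))

    node_arr = [np.vstack(nodes)]
    n_fixed = node_arr[0].shape[0]
    extra: list[np.ndarray] = []

    def add_node(p: np.ndarray) -> int:
        extra.append(p)
        return n_fixed + len(extra) - 1

    # connectors: peaks of ring j to the facing valleys of ring j+1
    conn_crowns = [(q * c) // design.n_connectors for q in range(design.n_connectors)]
    for j in range(n_rings - 1):
        for i in conn_crowns:
            # peak of ring j: where cos(c*theta - j*pi) = +1
            k0 = ((2 * i + (j % 2)) * nsub) % ring_n
            if design.connector_style == "peak-to-valley":
                # diagonal strut to the adjacent crown of the next ring
                k1 = (k0 + nsub) % ring_n
            else:
                k1 = k0  # same theta: valley of ring j+1
            n_a = ring_start[j] + k0
            n_b = ring_start[j + 1] + k1
            th0, th1 = theta[k0], theta[k0] + (theta[k1] - theta[k0]) % (2.0 * np.pi)
            za = node_arr[0][n_a, 2]
            zb = node_arr[0][n_b, 2]
            prev = n_a
            for s_i in range(1, nsub + 1):
                s = s_i / nsub
                th = th0 + (th1 - th0) * s
                if design.connector_style == "wavy":
                    th = th0 + _WAVY_AMPLITUDE_FRACTION * (2.0 * np.pi / c) * np.sin(
                        2.0 * np.pi * s
                    )
                z = za + (zb - za) * s
                if s_i == nsub:
                    nxt = n_b
                else:
                    nxt = add_node(np.array([R * np.cos(th), R * np.sin(th), z]))
                elems.append((prev, nxt))
                roles.append("connector")
                prev = nxt

    all_nodes = np.vstack(node_arr + [np.vstack(extra)]) if extra else node_arr[0]
    ne = len(elems)
    return BeamLattice(
        nodes=all_nodes,
        elements=np.array(elems, dtype=np.intp),
        width=np.full(ne, w_mm),
        thickness=np.full(ne, t_mm),
        role=np.array(roles),
        points_per_element=points_per_element,
        crown_nodes=np.array(sorted(set(crown)), dtype=np.intp),
    )


def toy_lattice(
    kind: str,
    n: int,
    length: float = 10.0,
    radius: float = 1.5,
    width: float = 0.2,
    thickness: float = 0.15,
    points_per_element: int = 4,
) -> BeamLattice:
    """Minimal lattices with known analytic behaviour, for verification.

    ``single_beam``: n nodes on a straight line of the given length along z.
    ``ring``: n nodes on a closed planar circle of the given radius.
    ``cube_graph``: n = k^3 grid points with unit spacing, axis-aligned
    edges (a diffusion fixture).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if kind == "single_beam":
        z = np.linspace(0.0, length, n)
        nodes = np.column_stack([np.zeros(n) + radius, np.zeros(n), z])
        elems = np.column_stack([np.arange(n - 1), np.arange(1, n)])
        role = np.array(["ring"] * (n - 1))
    elif kind == "ring":
        th = 2.0 * np.pi * np.arange(n) / n
        nodes = np.column_stack([radius * np.cos(th), radius * np.sin(th), np.zeros(n)])
        elems = np.column_stack([np.arange(n), (np.arange(n) + 1) % n])
        role = np.array(["ring"] * n)
    elif kind == "cube_graph":
        k = round(n ** (1.0 / 3.0))
        if k**3 != n:
            raise ValueError("cube_graph requires n to be a perfect cube")
        idx = np.arange(n).reshape(k, k, k)
        g = np.stack(np.meshgrid(np.arange(k), np.arange(k), np.arange(k), indexing="ij"), -1)
        nodes = g.reshape(-1, 3).astype(float)
        e = []
        for axis in range(3):
            a = np.moveaxis(idx, axis, 0)
            e.append(np.column_stack([a[:-1].ravel(), a[1:].ravel()]))
        elems = np.vstack(e)
        role = np.array(["ring"] * len(elems))
    else:
        raise ValueError("unknown toy lattice kind %r" % kind)
    ne = len(elems)
    return BeamLattice(
        nodes=nodes,
        elements=np.asarray(elems, dtype=np.intp),
        width=np.full(ne, width),
        thickness=np.full(ne, thickness),
        role=role,
        points_per_element=points_per_element,
    )
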