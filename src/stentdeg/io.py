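"""File I/O: index-series CSV, lattice CSV/VTK, state snapshots.

All formats are plain text.  VTK files use the legacy ASCII unstructured
format (line cells for struts, vertex cells for material-point snapshots)
and load in standard VTK readers.

Lattice CSV dialect
-------------------
Two sections introduced by header lines::

    # nodes: id,x_mm,y_mm,z_mm
    0,1.5,0.0,0.25
    ...
    # elements: id,n1,n2,width_mm,thickness_mm,role
    0,0,1,0.2,0.15,ring
    ...
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .degradation import PointState
from .geometry import BeamLattice
from .simulate import IndexSeries

__all__ = [
    "export_timeseries",
    "read_timeseries",
    "export_snapshot",
    "export_lattice_vtk",
    "export_lattice_csv",
    "read_lattice_csv",
]

_TS_HEADER = ["day", "beta_mean", "v_r", "sigma_mean_MPa", "D_mm"]


def export_timeseries(series: IndexSeries, path: str | Path) -> None:
    """Write the daily indices as CSV with the fixed header."""
    if len(series.day) == 0:
        raise ValueError("cannot export an empty index series")
    df = series.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


def read_timeseries(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != _TS_HEADER:
        raise ValueError(f"unexpected header {list(df.columns)}")
    return df


def export_snapshot(
    lattice: BeamLattice, state: PointState, path: str | Path, t: float = 0.0
) -> None:
    """VTK snapshot of the material points with their degradation state."""
    pts = lattice.point_positions()
    n = len(pts)
    lines = [
        "# vtk DataFile Version 3.0",
        f"stent material points, t={t:g} day",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in pts]
    lines.append(f"CELLS {n} {2 * n}")
    lines += [f"1 {i}" for i in range(n)]
    lines.append(f"CELL_TYPES {n}")
    lines += ["1"] * n  # VTK_VERTEX
    lines.append(f"POINT_DATA {n}")
    for name, arr in (
        ("beta", state.beta),
        ("C_m", state.c_m),
        ("sigma", state.sigma),
        ("alive", state.alive.astype(float)),
    ):
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.9g}" for v in arr]
    Path(path).write_text("\n".join(lines) + "\n")


def export_lattice_vtk(lattice: BeamLattice, path: str | Path) -> None:
    """VTK line-cell export of the beam lattice."""
    n = lattice.n_nodes
    e = lattice.n_elements
    lines = [
        "# vtk DataFile Version 3.0",
        "stent beam lattice",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in lattice.nodes]
    lines.append(f"CELLS {e} {3 * e}")
    lines += [f"2 {a} {b}" for a, b in lattice.elements]
    lines.append(f"CELL_TYPES {e}")
    lines += ["3"] * e  # VTK_LINE
    lines.append(f"CELL_DATA {e}")
    lines.append("SCALARS width double 1")
    lines.append("LOOKUP_TABLE default")
    lines += [f"{v:.9g}" for v in lattice.width]
    lines.append("SCALARS thickness double 1")
    lines.append("LOOKUP_TABLE default")
    lines += [f"{v:.9g}" for v in lattice.thickness]
    Path(path).write_text("\n".join(lines) + "\n")


def export_lattice_csv(lattice: BeamLattice, path: str | Path) -> None:
    out = ["# nodes: id,x_mm,y_mm,z_mm"]
    for i, p in enumerate(lattice.nodes):
        out.append(f"{i},{p[0]:.17g},{p[1]:.17g},{p[2]:.17g}")
    out.append("# elements: id,n1,n2,width_mm,thickness_mm,role")
    for i in range(lattice.n_elements):
        a, b = lattice.elements[i]
        out.append(
            f"{i},{a},{b},{lattice.width[i]:.17g},"
            f"{lattice.thickness[i]:.17g},{lattice.role[i]}"
        )
    Path(path).write_text("\n".join(out) + "\n")


def read_lattice_csv(path: str | Path, points_per_element: int = 4) -> BeamLattice:
    nodes, elems, width, thick, role = [], [], [], [], []
    section = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            section = "nodes" if "nodes" in line else "elements"
            continue
        parts = line.split(",")
        if section == "nodes":
            nodes.append([float(v) for v in parts[1:4]])
        elif section == "elements":
            elems.append([int(parts[1]), int(parts[2])])
            width.append(float(parts[3]))
            thick.append(float(parts[4]))
            role.append(parts[5])
        else:
            raise ValueError("malformed lattice CSV: data before a section header")
    return BeamLattice(
        nodes=np.array(nodes),
        elements=np.array(elems, dtype=np.intp),
        width=np.array(width),
        thickness=np.array(thick),
        role=np.array(role),
        points_per_element=points_per_element,
    )
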