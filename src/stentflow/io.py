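"""CSV and legacy-VTK (ASCII) export of geometries, grids, and fields.

The VTK writers emit the legacy text format (``# vtk DataFile Version
2.0``) directly; files open in ParaView/VisIt.  All tabular output goes
through pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ModelGeometry
from .mesh import StructuredGrid
from .solver import FieldSeries

__all__ = [
    "centerline_frame",
    "export_geometry_csv",
    "write_vtk_polylines",
    "write_vtk_structured_grid",
    "export_wss_profile_csv",
]


def centerline_frame(model: ModelGeometry) -> pd.DataFrame:
    """Tidy (s, x, y, h, segment) table of the centerline and half width."""
    cl = model.centerline
    return pd.DataFrame({
        "s": cl.s,
        "x": cl.points[:, 0],
        "y": cl.points[:, 1],
        "h": model.walls.h,
        "segment": cl.segment,
    })


def export_geometry_csv(model: ModelGeometry, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = centerline_frame(model)
    frame["x_upper"] = model.walls.upper[:, 0]
    frame["y_upper"] = model.walls.upper[:, 1]
    frame["x_lower"] = model.walls.lower[:, 0]
    frame["y_lower"] = model.walls.lower[:, 1]
    frame.to_csv(path, index=False)
    return path


def _vtk_header(f, title: str, dataset: str) -> None:
    f.write("# vtk DataFile Version 2.0\n")
    f.write(title[:255] + "\n")
    f.write("ASCII\n")
    f.write(f"DATASET {dataset}\n")


def write_vtk_polylines(polylines: dict, path) -> Path:
    """Named planar polylines (e.g. centerline + walls) as VTK POLYDATA."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pts = [np.asarray(p, float) for p in polylines.values()]
    n_total = sum(len(p) for p in pts)
    with open(path, "w") as f:
        _vtk_header(f, " + ".join(polylines), "POLYDATA")
        f.write(f"POINTS {n_total} float\n")
        for p in pts:
            for x, y in p:
                f.write(f"{x:.9g} {y:.9g} 0\n")
        size = sum(len(p) + 1 for p in pts)
        f.write(f"LINES {len(pts)} {size}\n")
        offset = 0
        for p in pts:
            ids = " ".join(str(offset + k) for k in range(len(p)))
            f.write(f"{len(p)} {ids}\n")
            offset += len(p)
    return path


def write_vtk_structured_grid(grid: StructuredGrid, path,
                              cell_data: dict | None = None) -> Path:
    """Grid (+ optional per-cell scalar fields) as VTK STRUCTURED_GRID."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ni, nj = grid.ni, grid.nj
    with open(path, "w") as f:
        _vtk_header(f, "stentflow structured grid", "STRUCTURED_GRID")
        f.write(f"DIMENSIONS {nj + 1} {ni + 1} 1\n")
        f.write(f"POINTS {(ni + 1) * (nj + 1)} float\n")
        for i in range(ni + 1):
            for j in range(nj + 1):
                x, y = grid.nodes[i, j]
                f.write(f"{x:.9g} {y:.9g} 0\n")
        if cell_data:
            f.write(f"CELL_DATA {ni * nj}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr, float)
                f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for i in range(ni):
                    for j in range(nj):
                        f.write(f"{arr[i, j]:.9g}\n")
    return path


def write_series_snapshot(series: FieldSeries, step: int, path) -> Path:
    """One saved time step (u, v, |u|, p) as a structured-grid VTK file."""
    speed = np.hypot(series.u[step], series.v[step])
    return write_vtk_structured_grid(series.grid, path, {
        "u": series.u[step], "v": series.v[step],
        "speed": speed, "p": series.p[step],
    })


def export_wss_profile_csv(wss_fields, path) -> Path:
    """Along-wall |wss| profiles as a tidy CSV (side, s, time, wss_pa)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    parts = []
    for f in np.atleast_1d(wss_fields):
        mag = f.magnitude
        tgrid, sgrid = np.meshgrid(f.times, f.s, indexing="ij")
        parts.append(pd.DataFrame({
            "side": f.side,
            "s": sgrid.ravel(),
            "time": tgrid.ravel(),
            "segment": np.tile(f.segment, len(f.times)),
            "wss_pa": mag.ravel(),
        }))
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)
    return path
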