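"""Body-fitted structured grids with near-wall boundary-layer grading.

The channel between the two wall contours is meshed by transfinite
interpolation along the local centerline normal: node (i, j) sits at
``c(s_i) + eta_j * h(s_i) * n(s_i)`` with ``eta_j`` in [-1, 1].  The
cross-channel distribution places a geometric stack of boundary layers at
each wall (five by default) and uniform cells in the core, mirroring the
near-wall refinement practice used to resolve the WSS-determining
velocity gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .geometry import ModelGeometry

__all__ = [
    "MeshConfig",
    "StructuredGrid",
    "generate_grid",
    "refine",
    "mesh_independence",
    "MeshIndependenceError",
]


@dataclass(frozen=True)
class MeshConfig:
    """Grid resolution parameters.

    axial_spacing : target cell length along the centerline (m)
    nj            : number of cross-channel cells
    n_layers      : boundary layers at each wall (study default 5)
    growth_ratio  : geometric growth of successive layer heights (>= 1)
    first_layer_fraction : first layer height / local channel width
    """

    axial_spacing: float = 1.0e-3
    nj: int = 14
    n_layers: int = 5
    growth_ratio: float = 1.2
    first_layer_fraction: float = 0.03

    def __post_init__(self) -> None:
        if self.axial_spacing <= 0:
            raise ValueError("axial spacing must be positive")
        if self.n_layers < 1:
            raise ValueError("need at least one boundary layer")
        if self.growth_ratio < 1.0:
            raise ValueError("growth ratio must be >= 1")
        if self.nj <= 2 * self.n_layers:
            raise ValueError("cross-channel count must exceed 2 x layer count")
        if not 0 < self.first_layer_fraction < 0.5 / self.n_layers:
            raise ValueError("first-layer fraction out of range")


def _eta_distribution(cfg: MeshConfig) -> np.ndarray:
    """Node positions across the unit-width channel, in [-1, 1]."""
    nl, r, f = cfg.n_layers, cfg.growth_ratio, cfg.first_layer_fraction
    layers = f * r ** np.arange(nl)            # heights / full width
    stack = layers.sum()
    n_core = cfg.nj - 2 * nl
    core_total = 1.0 - 2.0 * stack
    if core_total <= 0:
        raise ValueError("boundary layers thicker than the channel")
    heights = np.concatenate([layers, np.full(n_core, core_total / n_core),
                              layers[::-1]])
    eta = np.concatenate([[0.0], np.cumsum(heights)])
    eta[-1] = 1.0
    return 2.0 * eta - 1.0


@dataclass
class StructuredGrid:
    """Body-fitted quadrilateral grid between the wall contours.

    Nodes are indexed (i: axial 0..ni, j: cross-channel 0..nj); j = 0 is
    the lower wall, j = nj the upper wall.
    """

    nodes: np.ndarray          # (ni+1, nj+1, 2)
    station_s: np.ndarray      # (ni+1,) centerline arc length per axial node line
    cell_segment: np.ndarray   # (ni,) segment name of each axial cell column
    h: np.ndarray              # (ni+1,) local half width
    config: MeshConfig
    model: ModelGeometry | None = None

    @property
    def ni(self) -> int:
        return self.nodes.shape[0] - 1

    @property
    def nj(self) -> int:
        return self.nodes.shape[1] - 1

    @property
    def n_cells(self) -> int:
        return self.ni * self.nj

    def cell_areas(self) -> np.ndarray:
        X = self.nodes
        a = X[:-1, :-1]
        b = X[1:, :-1]
        c = X[1:, 1:]
        d = X[:-1, 1:]

        def cross(p, q):
            return p[..., 0] * q[..., 1] - p[..., 1] * q[..., 0]

        return 0.5 * (cross(b - a, d - a) + cross(d - c, b - c))

    def cell_centroids(self) -> np.ndarray:
        X = self.nodes
        return 0.25 * (X[:-1, :-1] + X[1:, :-1] + X[1:, 1:] + X[:-1, 1:])

    def segment_cell_mask(self, name: str) -> np.ndarray:
        return self.cell_segment == name


def _axial_stations(model: ModelGeometry, spacing: float) -> np.ndarray:
    """Axial node stations: uniform within each segment, exact at breaks."""
    path = model.centerline.path
    parts = []
    for k, seg in enumerate(path.segments):
        n = max(1, int(round(seg.length / spacing)))
        s = np.linspace(path.breaks[k], path.breaks[k + 1], n + 1)
        parts.append(s if k == 0 else s[1:])
    return np.concatenate(parts)


def generate_grid(model: ModelGeometry, cfg: MeshConfig) -> StructuredGrid:
    """Transfinite grid between the walls; raises on any non-positive cell."""
    s = _axial_stations(model, cfg.axial_spacing)
    path = model.centerline.path
    pts, _, normals, _ = path.evaluate(s)
    h = np.asarray(model.walls.h_fn(s), float)
    eta = _eta_distribution(cfg)
    nodes = (pts[:, None, :]
             + normals[:, None, :] * (eta[None, :, None] * h[:, None, None]))
    mid = 0.5 * (s[:-1] + s[1:])
    cell_segment = path.segment_name_at(mid)
    grid = StructuredGrid(nodes, s, cell_segment, h, cfg, model)
    areas = grid.cell_areas()
    if np.any(areas <= 0):
        i, j = np.unravel_index(int(np.argmin(areas)), areas.shape)
        raise ValueError(f"non-positive cell area at (i={i}, j={j})")
    return grid


def refine(cfg: MeshConfig, factor: float) -> MeshConfig:
    """Refined configuration: axial spacing / factor, nj * factor (layers kept)."""
    if not factor > 1:
        raise ValueError("refinement factor must exceed 1")
    return replace(
        cfg,
        axial_spacing=cfg.axial_spacing / factor,
        nj=int(math.ceil(cfg.nj * factor)),
        first_layer_fraction=cfg.first_layer_fraction / factor,
    )


class MeshIndependenceError(RuntimeError):
    def __init__(self, message: str, report: pd.DataFrame):
        super().__init__(message)
        self.report = report


def mesh_independence(
    model: ModelGeometry,
    ladder: Sequence[MeshConfig],
    monitor: Callable[[MeshConfig], float],
    tol: float = 0.05,
) -> tuple[MeshConfig, pd.DataFrame]:
    """Coarsest rung whose monitored value is within ``tol`` of the next rung.

    ``monitor`` maps a MeshConfig to the quantity watched for grid
    convergence (for the study: the solver's cycle-averaged third-segment
    velocity; see ``pipeline.velocity_monitor``).  Rungs are evaluated
    lazily coarse-to-fine and the first rung whose relative difference to
    the next-finer rung is below ``tol`` is selected.  Raises
    MeshIndependenceError (report attached) when no rung qualifies.
    """
    if len(ladder) < 2:
        raise ValueError("ladder needs at least two rungs")
    rows = []
    values: list[float] = []
    selected = None
    for k, cfg in enumerate(ladder):
        values.append(float(monitor(cfg)))
        rows.append({
            "rung": k,
            "axial_spacing": cfg.axial_spacing,
            "nj": cfg.nj,
            "n_cells": generate_grid(model, cfg).n_cells,
            "monitor_value": values[k],
            "rel_diff_to_next": np.nan,
        })
        if k >= 1:
            denom = abs(values[k])
            rel = abs(values[k] - values[k - 1]) / denom if denom else np.inf
            rows[k - 1]["rel_diff_to_next"] = rel
            if rel < tol:
                selected = ladder[k - 1]
                break
    report = pd.DataFrame(rows)
    if selected is None:
        raise MeshIndependenceError(
            f"no rung met the <{tol:.0%} velocity-difference rule", report
        )
    return selected, report


def default_ladder(base: MeshConfig | None = None, n_rungs: int = 4,
                   factor: float = 1.5) -> list[MeshConfig]:
    """Coarse-to-fine ladder obtained by repeated refinement of ``base``."""
    if base is None:
        base = MeshConfig()
    ladder = [base]
    for _ in range(n_rungs - 1):
        ladder.append(refine(ladder[-1], factor))
    return ladder
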