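"""Hemodynamic metrics: velocity and wall shear stress summaries.

The wall shear stress vector is the tangential part of the wall traction,

    wss = tau_t - (tau_t . n) n,

with the traction ``tau_t = sigma . n`` evaluated from the fluid stress
tensor ``sigma = -p I + mu (grad u + grad u^T)`` and ``n`` the outward
wall normal.  Velocity gradients at the wall are taken one-sidedly into
the two nearest boundary-layer cells (quadratic fit through the no-slip
wall value), which is why the mesh keeps a graded layer stack at each
wall.

Per-model summaries follow the study protocol: the third (stenosed)
segment is averaged at three cycle phases — waveform minimum, peak, and
mid-deceleration — and over the whole analyzed cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solver import FieldSeries, FluidProperties, Waveform

__all__ = [
    "WSSField",
    "SegmentMetrics",
    "ReductionTable",
    "wall_traction",
    "wss_project",
    "sample_phases",
    "segment_average_velocity",
    "segment_average_wss",
    "reduction",
    "build_reduction_table",
    "compute_segment_metrics",
]

PHASES = ("minimum", "peak", "intermediate")


@dataclass
class WSSField:
    """Wall traction and its tangential projection on one wall side.

    Arrays are (n_times, n_wall_faces); ``side`` is "lower" (j = 0) or
    "upper" (j = nj).
    """

    side: str
    s: np.ndarray              # (nf,) centerline arc length of wall faces
    segment: np.ndarray        # (nf,) segment tag
    face_length: np.ndarray    # (nf,)
    normal: np.ndarray         # (nf, 2) outward unit normal
    times: np.ndarray          # (nt,)
    traction: np.ndarray       # (nt, nf, 2)
    wss: np.ndarray            # (nt, nf, 2)

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.wss, axis=-1)


@dataclass(frozen=True)
class SegmentMetrics:
    """Third-segment summary for one model run."""

    group: str
    stenosis_degree: float
    stented: bool
    velocity_phases: dict          # phase name -> m/s
    velocity_cycle_avg: float      # m/s
    wss_phases: dict               # phase name -> Pa
    wss_cycle_avg: float           # Pa

    def as_row(self) -> dict:
        row = {
            "group": self.group,
            "stenosis": self.stenosis_degree,
            "stented": self.stented,
            "velocity_cycle_avg": self.velocity_cycle_avg,
            "wss_cycle_avg": self.wss_cycle_avg,
        }
        for k in PHASES:
            row[f"velocity_{k}"] = self.velocity_phases[k]
            row[f"wss_{k}"] = self.wss_phases[k]
        return row


@dataclass
class ReductionTable:
    """Pre/post-stent percentage reductions and their decomposition.

    ``cells``: one row per (group, stenosis) with velocity and WSS
    reductions in percent.  ``stenosis_variation``: per group, reduction
    at s = 0.70 minus at s = 0.40 (percentage points).
    ``tortuosity_variation``: per stenosis level, max minus min across
    groups (percentage points).
    """

    cells: pd.DataFrame
    stenosis_variation: pd.DataFrame
    tortuosity_variation: pd.DataFrame


def wss_project(traction: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Tangential projection ``tau_t - (tau_t . n) n`` (vectorized)."""
    traction = np.asarray(traction, float)
    normal = np.asarray(normal, float)
    norms = np.linalg.norm(normal, axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError("wall normals must be unit length")
    tn = np.sum(traction * normal, axis=-1, keepdims=True)
    return traction - tn * normal


def wall_traction(series: FieldSeries, fluid: FluidProperties | None = None,
                  side: str = "lower") -> WSSField:
    """Traction and WSS along one wall, for every saved time step.

    At a no-slip wall the velocity is identically zero along the wall, so
    its tangential derivative vanishes and the velocity gradient reduces
    to the wall-normal derivative, evaluated one-sidedly from the first
    two interior cell rows (quadratic through the wall).
    """
    fluid = fluid or series.fluid
    fvm = series.fvm
    grid = series.grid
    if grid.nj < 2:
        raise ValueError("need at least two interior cell rows for wall gradients")
    if side == "lower":
        Sw = -fvm.Sj[:, 0]                  # outward (out of fluid)
        fc = fvm.fcj[:, 0]
        C1, C2 = fvm.C[:, 0], fvm.C[:, 1]
        u1 = np.stack([series.u[:, :, 0], series.v[:, :, 0]], axis=-1)
        u2 = np.stack([series.u[:, :, 1], series.v[:, :, 1]], axis=-1)
        p1 = series.p[:, :, 0]
    elif side == "upper":
        Sw = fvm.Sj[:, -1]
        fc = fvm.fcj[:, -1]
        C1, C2 = fvm.C[:, -1], fvm.C[:, -2]
        u1 = np.stack([series.u[:, :, -1], series.v[:, :, -1]], axis=-1)
        u2 = np.stack([series.u[:, :, -2], series.v[:, :, -2]], axis=-1)
        p1 = series.p[:, :, -1]
    else:
        raise ValueError("side must be 'lower' or 'upper'")

    face_len = np.linalg.norm(Sw, axis=-1)
    n_out = Sw / face_len[:, None]
    n_in = -n_out
    d1 = np.sum((C1 - fc) * n_in, axis=-1)
    d2 = np.sum((C2 - fc) * n_in, axis=-1)
    # one-sided quadratic derivative at the wall (u_wall = 0)
    c1 = (d2**2 / (d1 * d2 * (d2 - d1)))
    c2 = (-(d1**2) / (d1 * d2 * (d2 - d1)))
    dudn = c1[None, :, None] * u1 + c2[None, :, None] * u2   # (nt, nf, 2)

    # grad u = dudn (x) n_in ; viscous traction mu (grad u + grad u^T) n_out
    dot_dn = np.sum(dudn * n_out[None], axis=-1)             # dudn . n_out
    nin_dot_nout = np.sum(n_in * n_out, axis=-1)             # = -1
    visc = fluid.viscosity * (
        dudn * nin_dot_nout[None, :, None] + dot_dn[..., None] * n_in[None])
    traction = -p1[..., None] * n_out[None] + visc
    wss = wss_project(traction, np.broadcast_to(n_out[None], traction.shape))

    mid_s = 0.5 * (grid.station_s[:-1] + grid.station_s[1:])
    return WSSField(
        side=side, s=mid_s, segment=grid.cell_segment,
        face_length=face_len, normal=n_out, times=series.times,
        traction=traction, wss=wss)


def sample_phases(series: FieldSeries, waveform: Waveform | None = None) -> dict:
    """Indices of the minimum, peak, and mid-deceleration phase snapshots.

    The intermediate phase is halfway between the peak and the following
    minimum; times are snapped to saved steps.  A constant waveform makes
    the three coincide (with a warning).
    """
    waveform = waveform or series.waveform
    T = waveform.period
    degenerate = False
    if {"minimum", "peak"} <= set(waveform.markers):
        t_min = waveform.markers["minimum"] % T
        t_max = waveform.markers["peak"] % T
    else:
        tt = np.linspace(0.0, T, 1024, endpoint=False)
        uu = np.asarray(waveform.mean_velocity(tt), float)
        if np.ptp(uu) < 1e-12 * max(1.0, np.abs(uu).max()):
            warnings.warn("constant waveform: the three phases coincide")
            t_min = t_max = 0.0
            degenerate = True
        else:
            t_min = float(tt[np.argmin(uu)])
            t_max = float(tt[np.argmax(uu)])
    if "intermediate" in waveform.markers:
        t_mid = waveform.markers["intermediate"] % T
    elif degenerate:
        t_mid = t_max
    else:
        t_mid = (t_max + 0.5 * ((t_min - t_max) % T)) % T

    phase_t = {"minimum": t_min, "peak": t_max, "intermediate": t_mid}
    step_phase = series.times % T
    out = {}
    for name, t in phase_t.items():
        circ = np.abs(step_phase - t % T)
        out[name] = int(np.argmin(np.minimum(circ, T - circ)))
    return out


def _segment_cell_selection(series: FieldSeries, segment):
    if isinstance(segment, str):
        mask = series.grid.segment_cell_mask(segment)
    else:
        mask = np.asarray(segment, bool)
    if not mask.any():
        raise ValueError("empty cell selection for segment average")
    return mask


def segment_average_velocity(series: FieldSeries, segment="arc3",
                             phases: dict | None = None):
    """Area-weighted mean velocity magnitude over a segment.

    Returns (per-phase dict or None, cycle average).  The cycle average
    is the Delta-t-weighted mean over the analyzed cycle (uniform steps,
    so the plain mean).
    """
    mask = _segment_cell_selection(series, segment)
    A = series.fvm.V[mask, :]
    speed = np.hypot(series.u[:, mask, :], series.v[:, mask, :])
    per_step = (speed * A).sum(axis=(1, 2)) / A.sum()
    cyc = float(per_step.mean())
    if phases is None:
        return None, cyc
    return {k: float(per_step[i]) for k, i in phases.items()}, cyc


def segment_average_wss(wss_fields, segment="arc3", phases: dict | None = None):
    """Arc-length-weighted mean |wss| over both walls of a segment."""
    fields = list(np.atleast_1d(wss_fields))
    num = 0.0
    den = 0.0
    for f in fields:
        mask = (f.segment == segment) if isinstance(segment, str) \
            else np.asarray(segment, bool)
        if not mask.any():
            raise ValueError("empty wall selection for segment average")
        w = f.face_length[mask]
        num = num + (f.magnitude[:, mask] * w).sum(axis=1)
        den = den + w.sum()
    per_step = num / den
    cyc = float(per_step.mean())
    if phases is None:
        return None, cyc
    return {k: float(per_step[i]) for k, i in phases.items()}, cyc


def reduction(pre: float, post: float) -> float:
    """Percentage reduction 100 (pre - post) / pre; negative = increase."""
    if not pre > 0:
        raise ValueError("pre-stent value must be positive")
    return 100.0 * (pre - post) / pre


def compute_segment_metrics(series: FieldSeries, group: str,
                            stenosis_degree: float, stented: bool,
                            segment: str = "arc3") -> SegmentMetrics:
    """Full per-model summary: velocity and WSS at phases + cycle average."""
    phases = sample_phases(series)
    vel_ph, vel_cyc = segment_average_velocity(series, segment, phases)
    walls = [wall_traction(series, side=s) for s in ("lower", "upper")]
    wss_ph, wss_cyc = segment_average_wss(walls, segment, phases)
    return SegmentMetrics(group, stenosis_degree, stented,
                          vel_ph, vel_cyc, wss_ph, wss_cyc)


def build_reduction_table(metrics) -> ReductionTable:
    """Pre/post reductions and the stenosis/tortuosity variation split.

    ``metrics`` is an iterable of SegmentMetrics covering the full
    3 x 4 x 2 study matrix; missing cells are reported by identity.
    """
    by_key = {}
    for m in metrics:
        by_key[(m.group, round(m.stenosis_degree, 2), m.stented)] = m
    groups = ("low", "medium", "high")
    stenoses = (0.40, 0.50, 0.60, 0.70)
    missing = [
        (g, s, st)
        for g in groups for s in stenoses for st in (False, True)
        if (g, s, st) not in by_key
    ]
    if missing:
        raise ValueError(f"incomplete study matrix; missing cells: {missing}")

    rows = []
    for g in groups:
        for s in stenoses:
            pre = by_key[(g, s, False)]
            post = by_key[(g, s, True)]
            rows.append({
                "group": g,
                "stenosis": s,
                "velocity_reduction_pct": reduction(
                    pre.velocity_cycle_avg, post.velocity_cycle_avg),
                "wss_reduction_pct": reduction(
                    pre.wss_cycle_avg, post.wss_cycle_avg),
            })
    cells = pd.DataFrame(rows)

    sten_rows = []
    for g in groups:
        sub = cells[cells.group == g].set_index("stenosis")
        sten_rows.append({
            "group": g,
            "velocity_pp": sub.loc[0.70, "velocity_reduction_pct"]
            - sub.loc[0.40, "velocity_reduction_pct"],
            "wss_pp": sub.loc[0.70, "wss_reduction_pct"]
            - sub.loc[0.40, "wss_reduction_pct"],
        })
    tort_rows = []
    for s in stenoses:
        sub = cells[cells.stenosis == s]
        tort_rows.append({
            "stenosis": s,
            "velocity_pp": sub.velocity_reduction_pct.max()
            - sub.velocity_reduction_pct.min(),
            "wss_pp": sub.wss_reduction_pct.max() - sub.wss_reduction_pct.min(),
        })
    return ReductionTable(cells, pd.DataFrame(sten_rows), pd.DataFrame(tort_rows))
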