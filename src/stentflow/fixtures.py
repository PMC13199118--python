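"""Deterministic synthetic inputs for every downstream stage.

Analytic velocity/pressure fields (Poiseuille, Womersley, uniform,
rigid translation) sampled onto grids as FieldSeries, canonical inlet
waveforms, straight-channel grids, and synthetic pre/post metric pairs
for the reduction-table builder.  Nothing here is random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import MeshConfig, StructuredGrid, _eta_distribution
from .metrics import SegmentMetrics, PHASES
from .solver import FieldSeries, FluidProperties, Waveform, _FVMesh, \
    womersley_reference

__all__ = [
    "AnalyticFieldSpec",
    "straight_channel_grid",
    "make_analytic_series",
    "make_waveform",
    "make_reduction_fixture",
]

#: Default pulsatile inlet: one-harmonic surrogate of a generic cardiac
#: cycle, U(t) = U0 (1 + 0.5 sin(2 pi t / T - pi/2)) — minimum at t = 0,
#: peak at t = T/2, cycle mean U0.
U0_DEFAULT = 0.2


def make_waveform(preset: str = "default", *, period: float = 1.0,
                  mean: float = U0_DEFAULT, amplitude: float = 0.5,
                  outlet_pressure=None) -> Waveform:
    """Named inlet waveform presets.

    ``default``: U0 (1 + a sin(2 pi t/T - pi/2)) with relative amplitude
    ``a`` (must keep U > 0); ``constant``: steady inflow at ``mean``.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    p_out = outlet_pressure if outlet_pressure is not None else (lambda t: 0.0)
    if preset == "constant" or amplitude == 0.0:
        u = float(mean)
        if u <= 0:
            raise ValueError("mean inlet velocity must be positive")
        return Waveform(
            period=period,
            mean_velocity=lambda t, u=u: np.full_like(
                np.asarray(t, float), u),
            outlet_pressure=p_out,
            markers={},
        )
    if preset != "default":
        raise ValueError(f"unknown waveform preset {preset!r}")
    if not 0 <= abs(amplitude) < 1:
        raise ValueError("relative amplitude must keep the waveform positive")

    def U(t, m=float(mean), a=float(amplitude), T=period):
        t = np.asarray(t, float)
        return m * (1.0 + a * np.sin(2.0 * np.pi * t / T - 0.5 * np.pi))

    return Waveform(
        period=period, mean_velocity=U, outlet_pressure=p_out,
        markers={"minimum": 0.0, "peak": 0.5 * period,
                 "intermediate": 0.75 * period},
    )


def straight_channel_grid(length: float = 3.0e-2, width: float = 3.0e-3,
                          cfg: MeshConfig | None = None,
                          segment: str = "arc3") -> StructuredGrid:
    """Rectangular channel grid with the standard cross-channel grading.

    All axial cells carry the given segment tag so segment-restricted
    metrics can be exercised on the whole channel.
    """
    cfg = cfg or MeshConfig()
    ni = max(2, int(round(length / cfg.axial_spacing)))
    x = np.linspace(0.0, length, ni + 1)
    eta = _eta_distribution(cfg)
    nodes = np.empty((ni + 1, cfg.nj + 1, 2))
    nodes[..., 0] = x[:, None]
    nodes[..., 1] = (0.5 * width * eta)[None, :]
    return StructuredGrid(
        nodes=nodes, station_s=x,
        cell_segment=np.array([segment] * ni),
        h=np.full(ni + 1, 0.5 * width), config=cfg, model=None)


@dataclass(frozen=True)
class AnalyticFieldSpec:
    """Closed-form field to sample: poiseuille | womersley | uniform |
    rigid-translation.

    ``mean_velocity`` drives poiseuille/uniform/rigid-translation;
    ``grad_amplitude`` and ``omega`` drive the oscillatory womersley
    field.  Fields are defined for straight channels aligned with x.
    """

    kind: str
    fluid: FluidProperties = field(default_factory=FluidProperties)
    mean_velocity: float = U0_DEFAULT
    grad_amplitude: float = 1.0e3     # Pa/m
    omega: float = 2.0 * np.pi        # rad/s
    direction: tuple = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("poiseuille", "womersley", "uniform",
                             "rigid-translation"):
            raise ValueError(f"unknown analytic field kind {self.kind!r}")


def _require_straight(grid: StructuredGrid) -> None:
    y_span = grid.nodes[..., 1].max(axis=1) - grid.nodes[..., 1].min(axis=1)
    x_var = np.ptp(grid.nodes[:, :, 0], axis=1)
    if np.any(x_var > 1e-9 * y_span.max()) or np.ptp(grid.h) > 1e-12:
        raise ValueError("analytic channel fields require a straight, "
                         "uniform-width grid aligned with x")


def make_analytic_series(spec: AnalyticFieldSpec, times,
                         grid: StructuredGrid) -> FieldSeries:
    """Sample a closed-form field on the grid at the given times."""
    times = np.atleast_1d(np.asarray(times, float))
    fvm = _FVMesh(grid)
    y = fvm.C[..., 1]
    x = fvm.C[..., 0]
    h = float(grid.h[0])
    nt = times.size
    mu = spec.fluid.viscosity
    U = spec.mean_velocity

    if spec.kind in ("uniform", "rigid-translation"):
        dx, dy = spec.direction
        nrm = np.hypot(dx, dy)
        u = np.full((nt,) + y.shape, U * dx / nrm)
        v = np.full((nt,) + y.shape, U * dy / nrm)
        p = np.zeros_like(u)
    elif spec.kind == "poiseuille":
        _require_straight(grid)
        prof = 1.5 * U * (1.0 - (y / h) ** 2)
        dpdx = -3.0 * mu * U / h**2
        u = np.broadcast_to(prof, (nt,) + y.shape).copy()
        v = np.zeros_like(u)
        p = np.broadcast_to(dpdx * (x - x.max()), (nt,) + y.shape).copy()
    else:  # womersley
        _require_straight(grid)
        uref = womersley_reference(spec.omega, h, spec.fluid,
                                   spec.grad_amplitude)
        u = np.stack([uref(y, t) for t in times])
        v = np.zeros_like(u)
        # dp/dx = -G cos(omega t)
        p = np.stack([
            -spec.grad_amplitude * np.cos(spec.omega * t) * (x - x.max())
            for t in times])

    width = 2.0 * h
    if spec.kind == "poiseuille":
        q = U * width
    elif spec.kind == "womersley":
        q = np.array([np.trapezoid(u[k, 0], y[0]) for k in range(nt)])
    else:
        q = U * spec.direction[0] / np.hypot(*spec.direction) * width
    qin = np.broadcast_to(q, (nt,)).astype(float)

    dt = float(times[1] - times[0]) if nt > 1 else 1.0
    return FieldSeries(
        grid=grid, fvm=fvm, times=times, u=u, v=v, p=p,
        inlet_flux=qin.copy(), outlet_flux=qin.copy(),
        continuity_residual=np.zeros(nt), dt=dt,
        period=2.0 * np.pi / spec.omega if spec.kind == "womersley" else 1.0,
        waveform=None, fluid=spec.fluid)


def make_reduction_fixture(target_reductions: dict,
                           pre_velocity: float = 1.0,
                           pre_wss: float = 10.0) -> list[SegmentMetrics]:
    """Synthetic pre/post SegmentMetrics realizing requested reductions.

    ``target_reductions`` maps (group, stenosis) to either a single
    percentage (applied to both metrics) or a (velocity_pct, wss_pct)
    pair; all values must be < 100.
    """
    out = []
    for (group, s), red in target_reductions.items():
        if np.ndim(red) == 0:
            rv = rw = float(red)
        else:
            rv, rw = map(float, red)
        if rv >= 100 or rw >= 100:
            raise ValueError("reductions must be below 100%")
        for stented, vel, wss in (
            (False, pre_velocity, pre_wss),
            (True, pre_velocity * (1 - rv / 100), pre_wss * (1 - rw / 100)),
        ):
            out.append(SegmentMetrics(
                group=group, stenosis_degree=s, stented=stented,
                velocity_phases={k: vel for k in PHASES},
                velocity_cycle_avg=vel,
                wss_phases={k: wss for k in PHASES},
                wss_cycle_avg=wss))
    return out
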