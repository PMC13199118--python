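#!/usr/bin/env python
"""Analytic verification of the flow solver: prints pass/fail per check.

Steady plane Poiseuille (velocity and wall shear), oscillatory
Womersley channel flow, mass-flux conservation, WSS orthogonality, and
pressure-datum invariance — the closed-form oracles the solver must
reproduce before the study results mean anything.
"""

import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from stentflow import fixtures, metrics, solver  # noqa: E402
from stentflow.mesh import MeshConfig  # noqa: E402


def check(name, value, bound):
    ok = value < bound
    print(f"  [{'PASS' if ok else 'FAIL'}] {name}: {value:.2e} < {bound:g}")
    return ok


def main() -> int:
    fluid = solver.FluidProperties()
    ok = True

    print("steady plane Poiseuille (default mesh):")
    grid = fixtures.straight_channel_grid(length=3e-2)
    wf = fixtures.make_waveform("constant", mean=0.2)
    ser = solver.solve_steady(grid, fluid, wf, tolerance=1e-8, max_outer=5000)
    i = int(grid.ni * 2 / 3)
    y = ser.fvm.C[i, :, 1]
    exact = 1.5 * 0.2 * (1 - (y / 1.5e-3) ** 2)
    ok &= check("velocity Linf error", np.abs(ser.u[0, i] - exact).max()
                / exact.max(), 0.02)
    w = metrics.wall_traction(ser, side="lower")
    tau = 6 * fluid.viscosity * 0.2 / 3e-3
    ok &= check("wall shear error vs 6*mu*U/H", abs(w.magnitude[0, i] - tau)
                / tau, 0.03)
    ok &= check("steady flux mismatch",
                solver.mass_flux_audit(ser).rel_mismatch.max(), 1e-6)
    dots = np.abs(np.sum(w.wss * w.normal[None], axis=-1))
    scale = np.maximum(np.linalg.norm(w.traction, axis=-1), 1e-30)
    ok &= check("wss . n orthogonality", float((dots / scale).max()), 1e-12)

    print("oscillatory Womersley channel flow:")
    h = 1.5e-3
    uref = solver.womersley_reference(2 * np.pi, h, fluid, 2e3)

    def profile(t, eta):
        return 1.5 * 0.1 * (1 - eta**2) + uref(eta * h, t)

    wfw = solver.Waveform(
        period=1.0,
        mean_velocity=lambda t: np.full_like(np.asarray(t, float), 0.1),
        profile=profile)
    gw = fixtures.straight_channel_grid(
        length=1.5e-2, width=2 * h,
        cfg=MeshConfig(axial_spacing=1e-3, nj=18, first_layer_fraction=0.025))
    serw = solver.simulate(gw, fluid, solver.SolverConfig(n_cycles=3), wfw)
    i = gw.ni // 2
    y = serw.fvm.C[i, :, 1]
    scale = max(np.abs(profile(t, y / h)).max() for t in serw.times)
    worst = max(np.abs(serw.u[k, i] - profile(serw.times[k], y / h)).max()
                for k in range(len(serw.times))) / scale
    ok &= check("profile error vs closed form", worst, 0.05)
    ok &= check("pulsatile flux mismatch",
                solver.mass_flux_audit(serw).rel_mismatch.max(), 1e-3)

    print("pressure-datum invariance:")
    grid = fixtures.straight_channel_grid(
        length=1e-2, cfg=MeshConfig(axial_spacing=1e-3))
    runs = []
    for p0 in (0.0, 1e4):
        wfp = fixtures.make_waveform("default",
                                     outlet_pressure=lambda t, p0=p0: p0)
        cfg = solver.SolverConfig(n_cycles=1, period=0.1, dt=0.01)
        runs.append(solver.simulate(grid, fluid, cfg, wfp))
    ok &= check("velocity change under +10 kPa datum",
                float(np.abs(runs[1].u - runs[0].u).max()), 1e-10)

    print("all checks passed" if ok else "SOME CHECKS FAILED")
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
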