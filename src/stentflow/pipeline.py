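"""Study orchestration: the 12-model matrix, pre/post stenting.

``run_study`` walks the requested cells of the 3 (tortuosity) x 4
(stenosis) matrix, simulates each cell pre- and post-stent on the study
mesh, summarizes the third segment, and assembles the reduction table
with its stenosis/tortuosity variation decomposition.  Runs are
resumable: each completed cell leaves a JSON summary that later
invocations reuse.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry
from .fixtures import make_waveform
from .mesh import MeshConfig, generate_grid, mesh_independence, default_ladder
from .metrics import (SegmentMetrics, ReductionTable, PHASES,
                      build_reduction_table, compute_segment_metrics)
from .solver import FluidProperties, SolverConfig, simulate, solve_steady

__all__ = [
    "StudyConfig",
    "StudyResult",
    "run_study",
    "steady_velocity_monitor",
    "cycle_average_monitor",
]

log = logging.getLogger(__name__)

_GROUPS = ("low", "medium", "high")


@dataclass(frozen=True)
class StudyConfig:
    """One self-contained description of a (partial) study run."""

    cells: tuple = tuple((g, s) for g in _GROUPS
                         for s in geometry.STUDY_STENOSES)
    mesh: MeshConfig = field(default_factory=MeshConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    waveform_preset: str = "default"
    waveform_mean: float = 0.2
    waveform_amplitude: float = 0.5
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for g, s in self.cells:
            if g not in _GROUPS:
                raise ValueError(f"unknown tortuosity group {g!r}")
            if round(s, 2) not in geometry.STUDY_STENOSES:
                raise ValueError(f"stenosis {s} not in the study set")

    def waveform(self):
        return make_waveform(self.waveform_preset, period=self.solver.period,
                             mean=self.waveform_mean,
                             amplitude=self.waveform_amplitude)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cells"] = [list(c) for c in self.cells]
        return d


@dataclass
class StudyResult:
    metrics: list
    table: ReductionTable | None
    n_simulated: int
    n_skipped: int
    failures: list


def _metrics_to_json(m: SegmentMetrics) -> dict:
    return m.as_row()


def _metrics_from_json(d: dict) -> SegmentMetrics:
    return SegmentMetrics(
        group=d["group"], stenosis_degree=float(d["stenosis"]),
        stented=bool(d["stented"]),
        velocity_phases={k: d[f"velocity_{k}"] for k in PHASES},
        velocity_cycle_avg=d["velocity_cycle_avg"],
        wss_phases={k: d[f"wss_{k}"] for k in PHASES},
        wss_cycle_avg=d["wss_cycle_avg"])


def run_one(group: str, s: float, stented: bool, cfg: StudyConfig
            ) -> SegmentMetrics:
    """Simulate one model and summarize its third segment."""
    model = geometry.make_model(group, s, stented)
    grid = generate_grid(model, cfg.mesh)
    series = simulate(grid, cfg.fluid, cfg.solver, cfg.waveform())
    return compute_segment_metrics(series, group, s, stented)


def run_study(cfg: StudyConfig) -> StudyResult:
    """Run the configured cells pre/post-stent and build the tables.

    Deterministic and idempotent: a cell whose JSON summary already
    exists in the output directory is not re-simulated.  Cell failures
    are recorded and do not stop the remaining cells; the reduction
    table is only built when the full 3 x 4 matrix is available.
    """
    outdir = Path(cfg.output_dir) if cfg.output_dir else None
    celldir = None
    if outdir is not None:
        celldir = outdir / "cells"
        celldir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.yaml").write_text(
            yaml.safe_dump(cfg.to_dict(), sort_keys=False))

    metrics, failures = [], []
    n_sim = n_skip = 0
    for g, s in cfg.cells:
        for stented in (False, True):
            label = f"{g}_s{int(round(100 * s)):02d}_" \
                    f"{'post' if stented else 'pre'}"
            cache = celldir / f"{label}.json" if celldir is not None else None
            if cache is not None and cache.exists():
                metrics.append(_metrics_from_json(
                    json.loads(cache.read_text())))
                n_skip += 1
                log.info("cell %s: reusing existing summary", label)
                continue
            try:
                m = run_one(g, s, stented, cfg)
            except Exception as exc:  # noqa: BLE001 - per-cell isolation
                log.error("cell %s failed: %s", label, exc)
                failures.append((label, str(exc)))
                continue
            metrics.append(m)
            n_sim += 1
            log.info("cell %s: velocity %.4f m/s, wss %.3f Pa",
                     label, m.velocity_cycle_avg, m.wss_cycle_avg)
            if cache is not None:
                cache.write_text(json.dumps(_metrics_to_json(m), indent=1))

    done = {(m.group, round(m.stenosis_degree, 2), m.stented) for m in metrics}
    complete = all((g, s, st) in done for g in _GROUPS
                   for s in geometry.STUDY_STENOSES for st in (False, True))
    table = build_reduction_table(metrics) if complete \
        else _partial_table(metrics)
    if outdir is not None:
        pd.DataFrame([m.as_row() for m in metrics]).to_csv(
            outdir / "metrics.csv", index=False)
        table.cells.to_csv(outdir / "reductions.csv", index=False)
        table.stenosis_variation.to_csv(
            outdir / "variations_stenosis.csv", index=False)
        table.tortuosity_variation.to_csv(
            outdir / "variations_tortuosity.csv", index=False)
    return StudyResult(metrics, table, n_sim, n_skip, failures)


def _partial_table(metrics) -> ReductionTable:
    """Reduction rows for whichever pre/post pairs are available."""
    from .metrics import reduction
    by_key = {(m.group, round(m.stenosis_degree, 2), m.stented): m
              for m in metrics}
    rows = []
    for (g, s, st), m in by_key.items():
        if st or (g, s, True) not in by_key:
            continue
        post = by_key[(g, s, True)]
        rows.append({
            "group": g, "stenosis": s,
            "velocity_reduction_pct": reduction(
                m.velocity_cycle_avg, post.velocity_cycle_avg),
            "wss_reduction_pct": reduction(
                m.wss_cycle_avg, post.wss_cycle_avg),
        })
    cols = ["group", "stenosis", "velocity_reduction_pct", "wss_reduction_pct"]
    cells = pd.DataFrame(rows, columns=cols)
    empty_s = pd.DataFrame(columns=["group", "velocity_pp", "wss_pp"])
    empty_t = pd.DataFrame(columns=["stenosis", "velocity_pp", "wss_pp"])
    return ReductionTable(cells, empty_s, empty_t)


# ---------------------------------------------------------------------------
# mesh-independence monitors


def steady_velocity_monitor(model, fluid: FluidProperties | None = None,
                            mean_velocity: float = 0.2):
    """Monitor: steady third-segment average velocity at the mean inflow.

    The grid-convergence question is spatial; freezing the inlet at the
    cycle-mean velocity makes each rung a sub-second steady solve while
    ranking meshes the same way as the cycle-averaged transient monitor.
    """
    fluid = fluid or FluidProperties()
    wf = make_waveform("constant", mean=mean_velocity)

    def monitor(mesh_cfg: MeshConfig) -> float:
        from .metrics import segment_average_velocity
        grid = generate_grid(model, mesh_cfg)
        series = solve_steady(grid, fluid, wf, tolerance=1e-6, max_outer=5000)
        return segment_average_velocity(series, "arc3")[1]

    return monitor


def cycle_average_monitor(model, cfg: StudyConfig | None = None):
    """Monitor: cycle-averaged third-segment velocity (full transient)."""
    cfg = cfg or StudyConfig()

    def monitor(mesh_cfg: MeshConfig) -> float:
        from .metrics import segment_average_velocity
        grid = generate_grid(model, mesh_cfg)
        series = simulate(grid, cfg.fluid, cfg.solver, cfg.waveform())
        return segment_average_velocity(series, "arc3")[1]

    return monitor


def select_study_mesh(model=None, ladder=None, tol: float = 0.05,
                      transient: bool = False):
    """Apply the <5% independence rule on the hardest cell.

    Returns (selected MeshConfig, report).  The study default equals the
    selected rung for the (high, 0.70, pre) model.
    """
    model = model or geometry.make_model("high", 0.70, False)
    ladder = ladder or default_ladder()
    monitor = (cycle_average_monitor(model) if transient
               else steady_velocity_monitor(model))
    return mesh_independence(model, ladder, monitor, tol=tol)
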