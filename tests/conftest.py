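import numpy as np
import pytest

from stentflow import fixtures, solver
from stentflow.mesh import MeshConfig
from stentflow.pipeline import StudyConfig, run_study


@pytest.fixture(scope="session")
def fluid():
    return solver.FluidProperties()


@pytest.fixture(scope="session")
def default_waveform():
    return fixtures.make_waveform("default")


@pytest.fixture(scope="session")
def poiseuille_steady(fluid):
    """Converged steady solve in a straight channel at the default mesh."""
    grid = fixtures.straight_channel_grid(length=3.0e-2, width=3.0e-3)
    wf = fixtures.make_waveform("constant", mean=0.2)
    series = solver.solve_steady(grid, fluid, wf, tolerance=1e-8,
                                 max_outer=5000)
    return grid, series


@pytest.fixture(scope="session")
def small_pulsatile(fluid, default_waveform):
    """Two-cycle pulsatile run on a compact curved model (low, s=0.50).

    Shared by the periodicity, flux-audit, and metrics tests; geometry
    extensions are shortened to keep the run to a few seconds.
    """
    from stentflow import geometry
    from stentflow.mesh import generate_grid

    model = geometry.make_model("low", 0.50, False,
                                inlet_extension=9e-3, outlet_extension=9e-3)
    grid = generate_grid(model, MeshConfig())
    cfg = solver.SolverConfig()
    series = solver.simulate(grid, fluid, cfg, default_waveform)
    return model, grid, series


@pytest.fixture(scope="session")
def study_result(tmp_path_factory):
    """The full 3 x 4 x 2 study matrix at the default study resolution.

    One shared run (~5 min); every study-law and bound check reads from
    this result.
    """
    outdir = tmp_path_factory.mktemp("study")
    res = run_study(StudyConfig(output_dir=str(outdir)))
    assert not res.failures, f"study cells failed: {res.failures}"
    return res
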