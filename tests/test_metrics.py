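"""WSS extraction, phase sampling, segment averages, reduction tables."""

import numpy as np
import pandas as pd
import pytest

from stentflow import fixtures, metrics, solver
from stentflow.fixtures import (AnalyticFieldSpec, make_analytic_series,
                                make_reduction_fixture, make_waveform,
                                straight_channel_grid)
from stentflow.mesh import MeshConfig


@pytest.fixture(scope="module")
def poiseuille_series(fluid):
    grid = straight_channel_grid(length=1e-2,
                                 cfg=MeshConfig(axial_spacing=5e-4, nj=18,
                                                first_layer_fraction=0.02))
    spec = AnalyticFieldSpec(kind="poiseuille", fluid=fluid,
                             mean_velocity=0.2)
    return make_analytic_series(spec, np.linspace(0.01, 1.0, 100), grid)


class TestWssProjection:
    def test_already_tangential(self):
        assert metrics.wss_project([1.0, 0.0], [0.0, 1.0]) == pytest.approx(
            [1.0, 0.0])

    def test_normal_traction_projects_to_zero(self):
        out = metrics.wss_project([0.0, -3.0], [0.0, 1.0])
        assert out == pytest.approx([0.0, 0.0], abs=1e-15)

    def test_mixed_traction(self):
        out = metrics.wss_project([3.0, 4.0], [0.0, 1.0])
        assert out == pytest.approx([3.0, 0.0])
        assert np.linalg.norm(out) == pytest.approx(3.0)

    def test_non_unit_normal_rejected(self):
        with pytest.raises(ValueError):
            metrics.wss_project([1.0, 0.0], [0.0, 2.0])


class TestWallTraction:
    def test_poiseuille_tangential_traction(self, poiseuille_series, fluid):
        tau_exact = 6 * fluid.viscosity * 0.2 / 3e-3
        for side in ("lower", "upper"):
            w = metrics.wall_traction(poiseuille_series, side=side)
            np.testing.assert_allclose(w.magnitude, tau_exact, rtol=0.01)

    def test_orthogonality_invariant(self, poiseuille_series):
        w = metrics.wall_traction(poiseuille_series, side="lower")
        dots = np.abs(np.sum(w.wss * w.normal[None], axis=-1))
        scale = np.linalg.norm(w.traction, axis=-1)
        assert (dots <= 1e-12 * np.maximum(scale, 1e-30)).all()

    def test_static_pressure_gives_pure_normal_traction(self, fluid):
        grid = straight_channel_grid(length=5e-3)
        spec = AnalyticFieldSpec(kind="uniform", fluid=fluid,
                                 mean_velocity=0.0)
        series = make_analytic_series(spec, [0.0], grid)
        series.p[:] = 250.0
        w = metrics.wall_traction(series, side="lower")
        np.testing.assert_allclose(
            w.traction, -250.0 * w.normal[None], atol=1e-12)
        np.testing.assert_allclose(w.wss, 0.0, atol=1e-12)

    def test_rigid_translation_has_zero_shear(self, fluid):
        # constant velocity field: all gradients vanish except through the
        # no-slip evaluation, which this fixture bypasses by construction
        grid = straight_channel_grid(length=5e-3)
        spec = AnalyticFieldSpec(kind="rigid-translation", fluid=fluid,
                                 mean_velocity=0.3, direction=(1.0, 0.0))
        series = make_analytic_series(spec, [0.0], grid)
        w = metrics.wall_traction(series, side="upper")
        # the one-sided fit through equal cell values and u_wall = 0 has
        # slope only from the wall condition; shear equals mu*u/d scale
        assert w.wss.shape == (1, grid.ni, 2)

    def test_pressure_offset_leaves_wss_unchanged(self, poiseuille_series):
        w0 = metrics.wall_traction(poiseuille_series, side="lower")
        shifted = poiseuille_series
        shifted.p = shifted.p + 7.5e3
        w1 = metrics.wall_traction(shifted, side="lower")
        np.testing.assert_allclose(w1.magnitude, w0.magnitude, atol=1e-10)


class TestSamplePhases:
    def test_default_waveform_phases(self, small_pulsatile):
        _, _, series = small_pulsatile
        idx = metrics.sample_phases(series)
        t = series.times
        T = series.period
        assert (t[idx["minimum"]] % T) in (pytest.approx(0.0, abs=0.011),
                                           pytest.approx(T, abs=0.011))
        assert t[idx["peak"]] % T == pytest.approx(0.5, abs=0.006)
        assert t[idx["intermediate"]] % T == pytest.approx(0.75, abs=0.006)

    def test_constant_waveform_degenerates_with_warning(self, fluid):
        grid = straight_channel_grid(length=5e-3)
        spec = AnalyticFieldSpec(kind="poiseuille", fluid=fluid)
        series = make_analytic_series(spec, np.linspace(0.01, 1, 100), grid)
        series.waveform = make_waveform("constant", mean=0.2)
        with pytest.warns(UserWarning, match="constant"):
            idx = metrics.sample_phases(series)
        assert len(set(idx.values())) == 1


class TestSegmentAverages:
    def test_uniform_field_average(self, fluid):
        grid = straight_channel_grid(length=5e-3)
        spec = AnalyticFieldSpec(kind="uniform", fluid=fluid,
                                 mean_velocity=1.0)
        series = make_analytic_series(spec, np.linspace(0, 1, 10), grid)
        ph, cyc = metrics.segment_average_velocity(
            series, "arc3", {"minimum": 0, "peak": 5, "intermediate": 7})
        assert cyc == pytest.approx(1.0, rel=1e-12)
        assert all(v == pytest.approx(1.0) for v in ph.values())

    def test_poiseuille_mean_speed(self, poiseuille_series):
        _, cyc = metrics.segment_average_velocity(poiseuille_series)
        assert cyc == pytest.approx(0.2, rel=0.01)

    def test_alternating_series_cycle_average(self, fluid):
        grid = straight_channel_grid(length=5e-3)
        spec = AnalyticFieldSpec(kind="uniform", fluid=fluid,
                                 mean_velocity=1.0)
        series = make_analytic_series(spec, np.linspace(0, 1, 10), grid)
        series.u[1::2] = 3.0
        series.u[::2] = 1.0
        series.v[:] = 0.0
        _, cyc = metrics.segment_average_velocity(series)
        assert cyc == pytest.approx(2.0, rel=1e-12)

    def test_uniform_wss_fixture(self, poiseuille_series):
        w = metrics.wall_traction(poiseuille_series, side="lower")
        w.wss = np.zeros_like(w.wss)
        w.wss[..., 0] = 2.0
        _, cyc = metrics.segment_average_wss([w])
        assert cyc == pytest.approx(2.0, rel=1e-12)

    def test_poiseuille_wss_and_viscosity_linearity(self, fluid):
        grid = straight_channel_grid(
            length=1e-2, cfg=MeshConfig(axial_spacing=5e-4, nj=18,
                                        first_layer_fraction=0.02))
        vals = {}
        for mu_scale in (1.0, 0.5):
            fl = solver.FluidProperties(
                density=fluid.density, viscosity=fluid.viscosity * mu_scale)
            spec = AnalyticFieldSpec(kind="poiseuille", fluid=fl,
                                     mean_velocity=0.2)
            series = make_analytic_series(spec, [0.0], grid)
            walls = [metrics.wall_traction(series, side=s)
                     for s in ("lower", "upper")]
            vals[mu_scale] = metrics.segment_average_wss(walls)[1]
        tau_exact = 6 * fluid.viscosity * 0.2 / 3e-3
        assert vals[1.0] == pytest.approx(tau_exact, rel=0.01)
        assert vals[0.5] == pytest.approx(0.5 * vals[1.0], rel=1e-9)

    def test_empty_selection_rejected(self, poiseuille_series):
        with pytest.raises(ValueError):
            metrics.segment_average_velocity(poiseuille_series, "arc1")


class TestReduction:
    def test_no_change(self):
        assert metrics.reduction(1.0, 1.0) == 0.0

    def test_sixty_percent(self):
        assert metrics.reduction(10.0, 4.0) == pytest.approx(60.0)

    def test_increase_reported_negative(self):
        assert metrics.reduction(4.0, 10.0) == pytest.approx(-150.0)

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(ValueError):
            metrics.reduction(0.0, 1.0)


class TestReductionTable:
    @staticmethod
    def _full_matrix(reduction_of):
        targets = {(g, s): reduction_of(g, s)
                   for g in ("low", "medium", "high")
                   for s in (0.40, 0.50, 0.60, 0.70)}
        return make_reduction_fixture(targets)

    def test_identical_cells_give_zero_variations(self):
        table = metrics.build_reduction_table(
            self._full_matrix(lambda g, s: 50.0))
        assert np.allclose(table.stenosis_variation.velocity_pp, 0.0)
        assert np.allclose(table.tortuosity_variation.wss_pp, 0.0)

    def test_stenosis_ramp_gives_thirty_points(self):
        ramp = {0.40: 40.0, 0.50: 50.0, 0.60: 60.0, 0.70: 70.0}
        table = metrics.build_reduction_table(
            self._full_matrix(lambda g, s: ramp[round(s, 2)]))
        assert np.allclose(table.stenosis_variation.velocity_pp, 30.0)
        assert np.allclose(table.tortuosity_variation.velocity_pp, 0.0)

    def test_group_spread_gives_three_points(self):
        spread = {"low": 41.0, "medium": 42.0, "high": 44.0}
        table = metrics.build_reduction_table(
            self._full_matrix(lambda g, s: spread[g]))
        assert np.allclose(table.tortuosity_variation.velocity_pp, 3.0)
        assert np.allclose(table.stenosis_variation.velocity_pp, 0.0)

    def test_missing_cells_listed(self):
        rows = self._full_matrix(lambda g, s: 50.0)
        incomplete = [m for m in rows
                      if not (m.group == "high"
                              and m.stenosis_degree == 0.70 and m.stented)]
        with pytest.raises(ValueError, match=r"high.*0\.7.*True"):
            metrics.build_reduction_table(incomplete)
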