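"""Vessel geometry: arcs, tortuosity, stenosis profile, straightening."""

import numpy as np
import pytest

from stentflow import geometry as G


def closed_form_index(angle):
    # four equal alternating arcs: arc/chord = (angle/2)/sin(angle/2)
    return (angle / 2) / np.sin(angle / 2)


class TestCenterline:
    def test_near_zero_curvature_limit_is_straight(self):
        spec = G.VesselSpec(arcs=tuple(
            G.ArcSpec(radius=1.0, angle=1e-4, turn=+1 if k % 2 == 0 else -1)
            for k in range(4)), taper_length=2e-5)
        cl = G.build_centerline(spec)
        assert G.tortuosity_index(cl) == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("angle", [np.pi / 2, 2.0, np.pi - 1e-6])
    def test_single_arc_index_matches_arc_chord_closed_form(self, angle):
        # quarter circle: (pi/2)/sqrt(2) ~ 1.1107; half circle limit: pi/2
        spec = G.group_spec("low", 0.0, False)
        arcs = list(spec.arcs)
        arcs[0] = G.ArcSpec(radius=8e-3, angle=angle, turn=+1)
        arcs[1] = G.ArcSpec(arcs[1].radius, arcs[1].angle, -1)
        cl = G.build_centerline(G.VesselSpec(arcs=tuple(arcs)))
        expected = (angle / 2) / np.sin(angle / 2)
        assert G.tortuosity_index(cl, "arc1") == pytest.approx(
            expected, rel=1e-6)

    def test_quarter_circle_value(self):
        assert (np.pi / 4) / np.sin(np.pi / 4) == pytest.approx(
            (np.pi / 2) / np.sqrt(2), rel=1e-12)

    def test_straight_extension_has_unit_index(self):
        cl = G.build_centerline(G.group_spec("medium", 0.0, False))
        assert G.tortuosity_index(cl, "inlet_ext") == pytest.approx(1.0)

    def test_degenerate_range_rejected(self):
        cl = G.build_centerline(G.group_spec("low", 0.0, False))
        with pytest.raises(ValueError):
            G.tortuosity_index(cl, (0.01, 0.01))

    def test_preset_ordering_for_all_stenoses(self):
        for s in G.STUDY_STENOSES:
            idx = {g: G.tortuosity_index(
                G.build_centerline(G.group_spec(g, s, False)))
                for g in ("low", "medium", "high")}
            assert idx["high"] > idx["medium"] > idx["low"]
            for g, target in (("low", 1.05), ("medium", 1.15), ("high", 1.30)):
                assert idx[g] == pytest.approx(target, abs=2e-4)

    def test_arc_length_consistency(self):
        for g in ("low", "medium", "high"):
            spec = G.group_spec(g, 0.5, False)
            cl = G.build_centerline(spec)
            analytic = (spec.inlet_extension + spec.outlet_extension
                        + sum(a.length for a in spec.arcs))
            assert cl.s[-1] == pytest.approx(analytic, rel=1e-6)

    def test_tangent_continuity(self):
        cl = G.build_centerline(G.group_spec("high", 0.7, False),
                                sampling=2e-4)
        t = cl.tangents
        jump = np.arccos(np.clip((t[:-1] * t[1:]).sum(1), -1, 1))
        assert jump.max() < 0.05

    def test_segment_tags_contiguous_and_ordered(self):
        cl = G.build_centerline(G.group_spec("low", 0.4, False))
        order = ["inlet_ext", "arc1", "arc2", "arc3", "arc4", "outlet_ext"]
        seen = [cl.segment[0]]
        for tag in cl.segment[1:]:
            if tag != seen[-1]:
                seen.append(tag)
        assert seen == order

    def test_tiny_radius_rejected(self):
        arcs = tuple(G.ArcSpec(radius=1.4e-3, angle=1.0,
                               turn=+1 if k % 2 == 0 else -1)
                     for k in range(4))
        with pytest.raises(ValueError, match="self-intersect"):
            G.build_centerline(G.VesselSpec(arcs=arcs, taper_length=1e-4))


class TestArcSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(radius=-1.0, angle=1.0, turn=1),
        dict(radius=1.0, angle=0.0, turn=1),
        dict(radius=1.0, angle=np.pi, turn=1),
        dict(radius=1.0, angle=1.0, turn=2),
    ])
    def test_invalid_arcs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            G.ArcSpec(**kwargs)

    def test_non_alternating_turns_rejected(self):
        arcs = tuple(G.ArcSpec(radius=8e-3, angle=1.0, turn=+1)
                     for _ in range(4))
        with pytest.raises(ValueError, match="alternate"):
            G.VesselSpec(arcs=arcs)


class TestHalfWidth:
    def test_zero_stenosis_identity(self):
        h = G.half_width_profile(G.group_spec("low", 0.0, False))
        s = np.linspace(0, 0.1, 50)
        assert np.allclose(h(s), 1.5e-3)

    def test_seventy_percent_minimum(self):
        spec = G.group_spec("medium", 0.7, False)
        h = G.half_width_profile(spec)
        cl = G.build_centerline(spec)
        lo, hi = cl.segment_range("arc3")
        vals = h(np.linspace(lo, hi, 400))
        assert vals.min() == pytest.approx(0.45e-3, rel=1e-9)

    def test_stented_restores_lumen(self):
        for s in G.STUDY_STENOSES:
            spec = G.group_spec("high", s, True)
            h = G.half_width_profile(spec)
            assert np.allclose(h(np.linspace(0, 0.1, 200)), 1.5e-3)

    def test_stenosis_locality(self):
        spec = G.group_spec("low", 0.6, False)
        cl = G.build_centerline(spec)
        h = G.half_width_profile(spec)
        lo, hi = cl.segment_range("arc3")
        outside = (cl.s < lo - 1e-9) | (cl.s > hi + 1e-9)
        assert np.allclose(h(cl.s)[outside], 1.5e-3)
        assert h(np.array([(lo + hi) / 2]))[0] < 1.5e-3

    def test_excessive_taper_rejected(self):
        with pytest.raises(ValueError, match="taper"):
            G.group_spec("low", 0.5, False, taper_length=7e-3)


class TestStraightening:
    def test_endpoints_and_tangents_preserved(self):
        pre = G.build_centerline(G.group_spec("high", 0.5, False))
        post = G.build_centerline(G.group_spec("high", 0.5, True))
        for cl_lo, cl_hi in [(pre, post)]:
            lo_pre, hi_pre = pre.segment_range("arc3")
            lo_post, hi_post = post.segment_range("arc3")
            p0_pre = pre.path.evaluate(np.array([lo_pre]))
            p0_post = post.path.evaluate(np.array([lo_post]))
            p1_pre = pre.path.evaluate(np.array([hi_pre]))
            p1_post = post.path.evaluate(np.array([hi_post]))
            for a, b in [(p0_pre, p0_post), (p1_pre, p1_post)]:
                np.testing.assert_allclose(a[0], b[0], atol=1e-12)  # points
                np.testing.assert_allclose(a[1], b[1], atol=1e-9)   # tangents

    def test_index_strictly_decreases_for_every_study_model(self):
        for g in ("low", "medium", "high"):
            for s in G.STUDY_STENOSES:
                pre = G.build_centerline(G.group_spec(g, s, False))
                post = G.straighten_third_segment(G.group_spec(g, s, True))
                assert (G.tortuosity_index(post, "arc3")
                        < G.tortuosity_index(pre, "arc3"))

    def test_nearly_straight_arc_blend_coincides(self):
        arcs = tuple(G.ArcSpec(radius=0.5, angle=0.01,
                               turn=+1 if k % 2 == 0 else -1)
                     for k in range(4))
        pre = G.build_centerline(G.VesselSpec(arcs=arcs))
        post = G.build_centerline(G.VesselSpec(arcs=arcs, stented=True))
        lo, hi = pre.segment_range("arc3")
        ss = np.linspace(lo, hi, 50)
        lo2, hi2 = post.segment_range("arc3")
        ss2 = np.linspace(lo2, hi2, 50)
        d = np.linalg.norm(pre.path.evaluate(ss)[0]
                           - post.path.evaluate(ss2)[0], axis=1)
        assert d.max() < 1e-7

    def test_requires_stented_flag(self):
        with pytest.raises(ValueError):
            G.straighten_third_segment(G.group_spec("low", 0.4, False))


class TestWalls:
    def test_offsets_are_half_width(self):
        m = G.make_model("medium", 0.6, False)
        gap = np.linalg.norm(m.walls.upper - m.walls.lower, axis=1)
        np.testing.assert_allclose(gap, 2 * m.walls.h, rtol=1e-12)

    def test_concentric_arc_offsets(self):
        # walls of a constant-width curved channel are concentric arcs
        spec = G.group_spec("high", 0.0, False)
        cl = G.build_centerline(spec)
        walls = G.build_walls(cl, G.half_width_profile(spec))
        m = cl.segment_mask("arc1")
        arc = cl.path.segments[1]
        r_up = np.linalg.norm(walls.upper[m] - arc.center, axis=1)
        r_lo = np.linalg.norm(walls.lower[m] - arc.center, axis=1)
        R, h = arc.radius, 1.5e-3
        assert np.allclose(sorted({round(r, 9) for r in r_up}), R - h) or \
            np.allclose(r_up, R - h) or np.allclose(r_up, R + h)
        assert {round(r_up[0] + r_lo[0], 6)} == {round(2 * R, 6)}

    def test_throat_gap(self):
        m = G.make_model("low", 0.7, False)
        gap = np.linalg.norm(m.walls.upper - m.walls.lower, axis=1)
        assert gap.min() == pytest.approx(0.3 * 3e-3, rel=1e-9)

    def test_offset_validity_all_study_geometries(self):
        for g, s, st in G.study_matrix():
            m = G.make_model(g, s, st)
            margin = 1 - np.abs(m.centerline.curvature) * m.walls.h
            assert margin.min() > 0.1

    def test_fold_over_rejected(self):
        spec = G.group_spec("high", 0.0, False)
        cl = G.build_centerline(spec)
        with pytest.raises(ValueError, match="curvature"):
            G.build_walls(cl, lambda s: np.full_like(
                np.atleast_1d(np.asarray(s, float)), 6e-3))


class TestMakeModel:
    def test_deterministic(self):
        a = G.make_model("low", 0.4, False)
        b = G.make_model("low", 0.4, False)
        assert np.array_equal(a.centerline.points, b.centerline.points)
        assert np.array_equal(a.walls.upper, b.walls.upper)

    def test_full_matrix_enumeration(self):
        assert len(G.study_matrix(stented=False)) == 12
        assert len(G.study_matrix()) == 24

    def test_stented_high_seventy(self):
        m = G.make_model("high", 0.7, True)
        assert np.allclose(m.walls.h, 1.5e-3)
        pre = G.make_model("high", 0.7, False)
        assert (G.tortuosity_index(m.centerline, "arc3")
                < G.tortuosity_index(pre.centerline, "arc3"))
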