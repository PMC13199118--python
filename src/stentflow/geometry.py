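"""Idealized tortuous coronary vessel geometry.

A vessel model is a planar channel built around a centerline composed of a
straight inlet extension, four circular arcs with alternating turn
direction, and a straight outlet extension.  Tortuosity is controlled by
arc curvature; a diameter stenosis narrows the third arc; stent
implantation is represented by straightening the third segment (cubic
Hermite blend between the unchanged neighbors) and restoring the lumen to
the nominal diameter.

All lengths are SI meters; the plane is x-y; centerline arc length ``s``
runs from the start of the inlet extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ArcSpec",
    "VesselSpec",
    "TortuosityGroup",
    "Centerline",
    "WallContours",
    "ModelGeometry",
    "TORTUOSITY_PRESETS",
    "STUDY_STENOSES",
    "D0_DEFAULT",
    "group_spec",
    "build_centerline",
    "tortuosity_index",
    "half_width_profile",
    "straighten_third_segment",
    "build_walls",
    "make_model",
]

#: Nominal lumen diameter of an epicardial coronary artery (m).
D0_DEFAULT = 3.0e-3

#: Diameter-stenosis degrees of the study matrix.
STUDY_STENOSES = (0.40, 0.50, 0.60, 0.70)

#: Segment names in order along the vessel.
SEGMENT_NAMES = ("inlet_ext", "arc1", "arc2", "arc3", "arc4", "outlet_ext")


@dataclass(frozen=True)
class ArcSpec:
    """One circular centerline arc.

    ``turn`` is +1 for a left turn and -1 for a right turn; curvature
    magnitude is ``1/radius``.
    """

    radius: float
    angle: float
    turn: int

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"arc radius must be positive, got {self.radius}")
        if not 0 < self.angle < np.pi:
            raise ValueError(f"arc angle must lie in (0, pi), got {self.angle}")
        if self.turn not in (+1, -1):
            raise ValueError(f"turn must be +1 or -1, got {self.turn}")

    @property
    def length(self) -> float:
        return self.radius * self.angle


@dataclass(frozen=True)
class VesselSpec:
    """Full parametric description of one vessel model."""

    arcs: tuple[ArcSpec, ArcSpec, ArcSpec, ArcSpec]
    base_diameter: float = D0_DEFAULT
    stenosis_degree: float = 0.0
    stented: bool = False
    inlet_extension: float = 10 * D0_DEFAULT
    outlet_extension: float = 10 * D0_DEFAULT
    taper_length: float = 0.5 * D0_DEFAULT

    def __post_init__(self) -> None:
        if len(self.arcs) != 4:
            raise ValueError("a vessel is composed of exactly four arcs")
        for a, b in zip(self.arcs[:-1], self.arcs[1:]):
            if a.turn == b.turn:
                raise ValueError("consecutive arcs must alternate turn sign")
        if not 0 <= self.stenosis_degree < 0.9:
            raise ValueError(
                f"stenosis degree must lie in [0, 0.9), got {self.stenosis_degree}"
            )
        if self.base_diameter <= 0:
            raise ValueError("base diameter must be positive")
        if self.inlet_extension < 0 or self.outlet_extension < 0:
            raise ValueError("extensions must be non-negative")
        third = self.arcs[2]
        if self.taper_length > 0.5 * third.length:
            raise ValueError(
                "taper length exceeds half the third-segment length "
                f"({self.taper_length} > {0.5 * third.length})"
            )


@dataclass(frozen=True)
class TortuosityGroup:
    """Named preset of four-arc radii/angles.

    For four equal arcs with alternating turns the chord vectors of the
    arcs are parallel, so the tortuosity index of the arc region has the
    closed form ``(angle/2) / sin(angle/2)``; the preset angles solve that
    expression for the target index.
    """

    label: str
    radius: float
    angle: float

    def arcs(self) -> tuple[ArcSpec, ArcSpec, ArcSpec, ArcSpec]:
        return tuple(
            ArcSpec(self.radius, self.angle, +1 if k % 2 == 0 else -1)
            for k in range(4)
        )

    @property
    def analytic_index(self) -> float:
        x = 0.5 * self.angle
        return x / np.sin(x)


# Equal arc length 4*D0 per arc so curvature is the only variable across
# groups; angles give four-arc tortuosity indices 1.05 / 1.15 / 1.30.
TORTUOSITY_PRESETS: dict[str, TortuosityGroup] = {
    "low": TortuosityGroup("low", radius=1.1144e-2, angle=1.076823),
    "medium": TortuosityGroup("medium", radius=6.645e-3, angle=1.805767),
    "high": TortuosityGroup("high", radius=4.912e-3, angle=2.442992),
}


def group_spec(
    group: str | TortuosityGroup,
    stenosis_degree: float,
    stented: bool,
    **overrides,
) -> VesselSpec:
    """VesselSpec for one cell of the study matrix."""
    if isinstance(group, str):
        group = TORTUOSITY_PRESETS[group]
    return VesselSpec(
        arcs=group.arcs(),
        stenosis_degree=stenosis_degree,
        stented=stented,
        **overrides,
    )


# ---------------------------------------------------------------------------
# analytic centerline path


class _Segment:
    """Analytic planar curve segment parameterized by local arc length."""

    name: str
    length: float

    def evaluate(self, s: np.ndarray):
        """Return (points (n,2), tangents (n,2), signed curvature (n,))."""
        raise NotImplementedError


class _Straight(_Segment):
    def __init__(self, name, start, direction, length):
        self.name = name
        self.start = np.asarray(start, float)
        self.direction = np.asarray(direction, float)
        self.length = float(length)

    def evaluate(self, s):
        s = np.atleast_1d(np.asarray(s, float))
        pts = self.start[None, :] + s[:, None] * self.direction[None, :]
        tans = np.broadcast_to(self.direction, pts.shape).copy()
        return pts, tans, np.zeros_like(s)

    @property
    def end(self):
        return self.start + self.length * self.direction

    @property
    def end_heading(self):
        return float(np.arctan2(self.direction[1], self.direction[0]))


class _Arc(_Segment):
    def __init__(self, name, start, heading, radius, angle, turn):
        self.name = name
        self.start = np.asarray(start, float)
        self.heading = float(heading)
        self.radius = float(radius)
        self.angle = float(angle)
        self.turn = int(turn)
        self.length = self.radius * self.angle
        # center lies at distance R along the left(+)/right(-) normal
        n = np.array([-np.sin(heading), np.cos(heading)]) * turn
        self.center = self.start + self.radius * n

    def evaluate(self, s):
        s = np.atleast_1d(np.asarray(s, float))
        phi = self.heading + self.turn * s / self.radius
        # position: center - R * (left normal of current heading) * turn
        nx, ny = -np.sin(phi), np.cos(phi)
        pts = np.stack(
            [
                self.center[0] - self.radius * self.turn * nx,
                self.center[1] - self.radius * self.turn * ny,
            ],
            axis=1,
        )
        tans = np.stack([np.cos(phi), np.sin(phi)], axis=1)
        curv = np.full_like(s, self.turn / self.radius)
        return pts, tans, curv

    @property
    def end(self):
        return self.evaluate(np.array([self.length]))[0][0]

    @property
    def end_heading(self):
        return self.heading + self.turn * self.angle


class _Hermite(_Segment):
    """Cubic Hermite blend, reparameterized to arc length via a dense LUT."""

    _N_LUT = 2001

    def __init__(self, name, p0, p1, t0, t1):
        self.name = name
        self.p0 = np.asarray(p0, float)
        self.p1 = np.asarray(p1, float)
        chord = float(np.linalg.norm(self.p1 - self.p0))
        self.m0 = np.asarray(t0, float) * chord
        self.m1 = np.asarray(t1, float) * chord
        xi = np.linspace(0.0, 1.0, self._N_LUT)
        speed = np.linalg.norm(self._deriv(xi), axis=1)
        from scipy.integrate import cumulative_trapezoid

        arc = cumulative_trapezoid(speed, xi, initial=0.0)
        self.length = float(arc[-1])
        self._xi_of_s = lambda s, arc=arc, xi=xi: np.interp(s, arc, xi)

    def _point(self, xi):
        xi = xi[:, None]
        h00 = 2 * xi**3 - 3 * xi**2 + 1
        h10 = xi**3 - 2 * xi**2 + xi
        h01 = -2 * xi**3 + 3 * xi**2
        h11 = xi**3 - xi**2
        return h00 * self.p0 + h10 * self.m0 + h01 * self.p1 + h11 * self.m1

    def _deriv(self, xi):
        xi = xi[:, None]
        d00 = 6 * xi**2 - 6 * xi
        d10 = 3 * xi**2 - 4 * xi + 1
        d01 = -6 * xi**2 + 6 * xi
        d11 = 3 * xi**2 - 2 * xi
        return d00 * self.p0 + d10 * self.m0 + d01 * self.p1 + d11 * self.m1

    def _deriv2(self, xi):
        xi = xi[:, None]
        return (
            (12 * xi - 6) * self.p0
            + (6 * xi - 4) * self.m0
            + (-12 * xi + 6) * self.p1
            + (6 * xi - 2) * self.m1
        )

    def evaluate(self, s):
        s = np.atleast_1d(np.asarray(s, float))
        xi = np.asarray(self._xi_of_s(np.clip(s, 0.0, self.length)))
        pts = self._point(xi)
        d1 = self._deriv(xi)
        d2 = self._deriv2(xi)
        speed = np.linalg.norm(d1, axis=1)
        tans = d1 / speed[:, None]
        curv = (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]) / speed**3
        return pts, tans, curv

    @property
    def end(self):
        return self.p1

    @property
    def end_heading(self):
        d = self._deriv(np.array([1.0]))[0]
        return float(np.arctan2(d[1], d[0]))


class _PlanarPath:
    """Piecewise-analytic centerline with exact arc-length parameterization."""

    def __init__(self, segments: Sequence[_Segment]):
        self.segments = list(segments)
        self.breaks = np.concatenate([[0.0], np.cumsum([g.length for g in segments])])
        self.length = float(self.breaks[-1])
        self.names = [g.name for g in segments]

    def segment_range(self, name: str) -> tuple[float, float]:
        k = self.names.index(name)
        return float(self.breaks[k]), float(self.breaks[k + 1])

    def evaluate(self, s):
        """(points, tangents, left-normals, signed curvature) at global s."""
        s = np.atleast_1d(np.asarray(s, float))
        s = np.clip(s, 0.0, self.length)
        idx = np.clip(np.searchsorted(self.breaks, s, side="right") - 1, 0,
                      len(self.segments) - 1)
        pts = np.empty((s.size, 2))
        tans = np.empty((s.size, 2))
        curv = np.empty(s.size)
        for k, seg in enumerate(self.segments):
            m = idx == k
            if not m.any():
                continue
            p, t, c = seg.evaluate(s[m] - self.breaks[k])
            pts[m], tans[m], curv[m] = p, t, c
        normals = np.stack([-tans[:, 1], tans[:, 0]], axis=1)
        return pts, tans, normals, curv

    def segment_name_at(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, float))
        idx = np.clip(np.searchsorted(self.breaks, s, side="right") - 1, 0,
                      len(self.segments) - 1)
        return np.array([self.names[k] for k in idx])


def _build_path(spec: VesselSpec) -> _PlanarPath:
    segs: list[_Segment] = []
    start = np.zeros(2)
    heading = 0.0
    if spec.inlet_extension > 0:
        seg = _Straight("inlet_ext", start, np.array([1.0, 0.0]), spec.inlet_extension)
        segs.append(seg)
        start = seg.end
    arc_segs = []
    for k, a in enumerate(spec.arcs):
        seg = _Arc(f"arc{k + 1}", start, heading, a.radius, a.angle, a.turn)
        arc_segs.append(seg)
        segs.append(seg)
        start, heading = seg.end, seg.end_heading
    if spec.stented:
        # replace the third arc by a cubic Hermite blend that keeps the
        # endpoints and end tangents of the neighbors
        old = arc_segs[2]
        t0 = np.array([np.cos(old.heading), np.sin(old.heading)])
        phi1 = old.end_heading
        t1 = np.array([np.cos(phi1), np.sin(phi1)])
        blend = _Hermite("arc3", old.start, old.end, t0, t1)
        segs[segs.index(old)] = blend
    if spec.outlet_extension > 0:
        direction = np.array([np.cos(heading), np.sin(heading)])
        segs.append(_Straight("outlet_ext", start, direction, spec.outlet_extension))
    return _PlanarPath(segs)


# ---------------------------------------------------------------------------
# public containers


@dataclass
class Centerline:
    """Discretely sampled centerline with its analytic path attached."""

    path: _PlanarPath
    s: np.ndarray            # (n,) strictly increasing arc length
    points: np.ndarray       # (n, 2)
    tangents: np.ndarray     # (n, 2) unit
    normals: np.ndarray      # (n, 2) unit left normals
    curvature: np.ndarray    # (n,) signed
    segment: np.ndarray      # (n,) segment name per sample

    def segment_range(self, name: str) -> tuple[float, float]:
        return self.path.segment_range(name)

    def segment_mask(self, name: str) -> np.ndarray:
        lo, hi = self.segment_range(name)
        return (self.s >= lo - 1e-12) & (self.s <= hi + 1e-12)


@dataclass
class WallContours:
    """Upper/lower wall polylines offset from the centerline by +-h(s)."""

    centerline: Centerline
    h: np.ndarray            # (n,) half width at each centerline sample
    upper: np.ndarray        # (n, 2)
    lower: np.ndarray        # (n, 2)
    h_fn: Callable[[np.ndarray], np.ndarray] = field(repr=False, default=None)


@dataclass
class ModelGeometry:
    """One cell of the study matrix: spec + centerline + walls."""

    group: str
    stenosis_degree: float
    stented: bool
    spec: VesselSpec
    centerline: Centerline
    walls: WallContours

    @property
    def label(self) -> str:
        state = "post" if self.stented else "pre"
        return f"{self.group}_s{int(round(100 * self.stenosis_degree)):02d}_{state}"


# ---------------------------------------------------------------------------
# operations


def build_centerline(spec: VesselSpec, sampling: float = 2.0e-4) -> Centerline:
    """Sample the vessel centerline at spacing ``sampling`` (m).

    Segment boundaries always coincide with samples so segment tags are
    contiguous and exact.  Raises if an arc radius would make the offset
    walls self-intersect (radius <= D0/2).
    """
    for a in spec.arcs:
        if a.radius <= 0.5 * spec.base_diameter:
            raise ValueError(
                f"arc radius {a.radius} <= half diameter "
                f"{0.5 * spec.base_diameter}: offset walls would self-intersect"
            )
    path = _build_path(spec)
    s_parts = []
    for k, seg in enumerate(path.segments):
        n = max(2, int(np.ceil(seg.length / sampling)) + 1)
        s_local = np.linspace(path.breaks[k], path.breaks[k + 1], n)
        if k > 0:
            s_local = s_local[1:]
        s_parts.append(s_local)
    s = np.concatenate(s_parts)
    pts, tans, norms, curv = path.evaluate(s)
    # tag boundary samples with the segment they end (left-continuous), so
    # tags are contiguous runs in order
    seg_names = path.segment_name_at(np.minimum(s, path.length) - 1e-12)
    seg_names[0] = path.names[0]
    return Centerline(path, s, pts, tans, norms, curv, seg_names)


def tortuosity_index(centerline: Centerline,
                     srange: tuple[float, float] | str | None = None) -> float:
    """Arc length over chord length of a centerline portion (>= 1).

    ``srange`` may be a segment name, an (s_lo, s_hi) pair, or None for the
    four-arc region (arc1 start to arc4 end).
    """
    if srange is None:
        lo = centerline.segment_range("arc1")[0]
        hi = centerline.segment_range("arc4")[1]
    elif isinstance(srange, str):
        lo, hi = centerline.segment_range(srange)
    else:
        lo, hi = srange
    if not hi > lo:
        raise ValueError(f"degenerate range ({lo}, {hi})")
    p_lo = centerline.path.evaluate(np.array([lo]))[0][0]
    p_hi = centerline.path.evaluate(np.array([hi]))[0][0]
    chord = float(np.linalg.norm(p_hi - p_lo))
    if chord == 0.0:
        raise ValueError("zero-length chord in tortuosity index")
    return (hi - lo) / chord


def half_width_profile(spec: VesselSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Half-width h(s) along the centerline.

    h = D0/2 outside the third segment; inside, cosine shoulders of length
    ``taper_length`` take it down to (1-s)*D0/2.  A stented vessel has the
    lumen restored: h = D0/2 everywhere.
    """
    path = _build_path(spec)
    h0 = 0.5 * spec.base_diameter
    if spec.stented or spec.stenosis_degree == 0.0:
        return lambda s: np.full_like(np.atleast_1d(np.asarray(s, float)), h0)
    lo, hi = path.segment_range("arc3")
    tl = spec.taper_length
    h_min = (1.0 - spec.stenosis_degree) * h0

    def h(s):
        s = np.atleast_1d(np.asarray(s, float))
        out = np.full_like(s, h0)
        inside = (s >= lo) & (s <= hi)
        # ramp factor 0 -> 1 over each shoulder, 1 on the plateau
        t = np.minimum(np.minimum(s - lo, hi - s) / tl, 1.0)
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.clip(t, 0.0, 1.0)))
        out[inside] = h0 + (h_min - h0) * ramp[inside]
        return out

    return h


def straighten_third_segment(spec: VesselSpec, sampling: float = 2.0e-4) -> Centerline:
    """Centerline with the third arc replaced by a Hermite straightening blend."""
    if not spec.stented:
        raise ValueError("straighten_third_segment requires spec.stented = True")
    return build_centerline(spec, sampling)


def build_walls(centerline: Centerline,
                h: Callable[[np.ndarray], np.ndarray]) -> WallContours:
    """Offset wall contours at +-h(s) along the centerline normals.

    Raises if anywhere h >= local radius of curvature (offset walls would
    fold over).
    """
    hv = np.asarray(h(centerline.s), float)
    if np.any(hv <= 0):
        raise ValueError("half width must be positive everywhere")
    margin = 1.0 - np.abs(centerline.curvature) * hv
    if np.any(margin <= 0):
        k = int(np.argmin(margin))
        raise ValueError(
            f"wall offset exceeds radius of curvature at s={centerline.s[k]:.5f}"
        )
    upper = centerline.points + centerline.normals * hv[:, None]
    lower = centerline.points - centerline.normals * hv[:, None]
    return WallContours(centerline, hv, upper, lower, h_fn=h)


def make_model(group: str | TortuosityGroup, stenosis_degree: float,
               stented: bool, sampling: float = 2.0e-4, **overrides) -> ModelGeometry:
    """Assemble one study geometry (deterministic for identical inputs)."""
    if isinstance(group, TortuosityGroup):
        label = group.label
    else:
        label = group
    spec = group_spec(group, stenosis_degree, stented, **overrides)
    cl = build_centerline(spec, sampling)
    h = half_width_profile(spec)
    walls = build_walls(cl, h)
    return ModelGeometry(label, stenosis_degree, stented, spec, cl, walls)


def study_matrix(stented: bool | None = None) -> list[tuple[str, float, bool]]:
    """Enumerate the study cells: 3 groups x 4 stenoses (x 2 if stented None)."""
    states = (False, True) if stented is None else (stented,)
    return [
        (g, s, st)
        for g in ("low", "medium", "high")
        for s in STUDY_STENOSES
        for st in states
    ]
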