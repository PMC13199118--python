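# Methods

## The question the pipeline answers

Stenting a tortuous, stenosed coronary segment does two things to the
local geometry at once: it restores the lumen and it straightens the
vessel.  Both change the local velocity field and the wall shear stress
(WSS), and chronically lowered WSS is the leading hemodynamic candidate
mechanism for in-stent restenosis.  The pipeline quantifies how much of
the post-stent *reduction* in velocity and WSS is attributable to the
severity of the treated stenosis versus the tortuosity of the vessel,
on an idealized geometry family where the two factors can be varied
independently: three tortuosity levels × four diameter-stenosis degrees
(40/50/60/70%), each simulated pre- and post-stent.

## Geometry model

A vessel is a planar channel around a centerline composed of a straight
inlet extension, four circular arcs with alternating turn direction,
and a straight outlet extension.

* **Planar 2-D channel, not a 3-D tube.**  Every quantity the study
  reports is an internal pre/post ratio (a percentage reduction), and
  the mechanics that drive those ratios — continuity through a narrowed
  lumen, the steepening of the near-wall velocity gradient, curvature-
  induced asymmetry of the core flow — are all present in a planar
  channel.  The 2-D choice keeps a full cardiac cycle to seconds of
  wall time, so the whole 24-run matrix is re-computable on one CPU in
  minutes.  Absolute magnitudes of the reductions differ from a 3-D
  tube (cross-sectional area scales with diameter, not diameter²), so
  comparisons against 3-D reference values are made as one-sided
  bounds, never equalities.
* **Dimensions.**  Nominal diameter D0 = 3 mm (typical epicardial
  coronary), extensions 10·D0 at each end so the prescribed inlet
  profile is decoupled from the curved region.
* **Tortuosity presets.**  Each arc has the same arc length, 4·D0 =
  12 mm, so curvature is the *only* variable across groups and the
  lesion length is identical everywhere.  For four equal alternating
  arcs the individual chord vectors are parallel, which gives the
  closed form tortuosity index T = (θ/2)/sin(θ/2); the preset angles
  (61.7°, 103.5°, 140.0°) solve this for T = 1.05 (low), 1.15
  (medium), 1.30 (high), spanning mild to severe clinical tortuosity.
  The corresponding radii (11.1, 6.6, 4.9 mm) keep the wall offset
  valid with margin (curvature × half-width ≤ 0.31).
* **Stenosis.**  The whole third arc is narrowed to (1−s)·D0 — the
  stenosis is formed by changing the *diameter of the arc*, not by a
  local throat — with cosine shoulders of length D0/2 at each end as
  numerical smoothing.  Short shoulders matter: long tapers would turn
  the whole-arc narrowing into a localized constriction and dilute the
  segment-averaged metrics.
* **Stent surrogate.**  The post-stent vessel replaces the third arc by
  a cubic Hermite blend between the unchanged endpoints, matching the
  end tangents of the neighboring arcs (so the centerline remains
  tangent-continuous), and restores the lumen to D0.  Lumen restoration
  is required for the observed physics: post-stent velocity falls
  relative to pre-stent in proportion to s, which straightening alone
  could not produce.  The blend fixes the endpoints (chord-preserving);
  whether a real stent preserves chord or arc length is not modeled.

## Mesh

Transfinite interpolation between the exact wall offsets along the
analytic centerline normals: node (i, j) = c(s_i) + η_j·h(s_i)·n(s_i).
The cross-channel distribution carries five geometrically graded
boundary layers at each wall (growth ratio 1.2, first layer 3% of the
local width) and uniform core cells; the five-layer stack is what makes
the one-sided WSS gradient evaluation reliable.

The study resolution is *derived*, not assumed, by the grid-convergence
rule used for the reference study: a mesh is accepted when the
monitored third-segment average velocity differs from the next-denser
mesh by less than 5%.  On the hardest cell (high tortuosity, s = 0.70,
pre-stent) the base rung of the default ladder (axial spacing 1 mm,
nj = 14, ≈1 500 cells) differs from the next rung (0.67 mm, nj = 21) by
1.2%, so the base rung is selected and used uniformly for all cells for
comparability (analysis/02).  The monitored quantity for the
per-geometry sweep is the steady solution at the cycle-mean inflow —
grid convergence is a spatial question, and the steady monitor ranks
meshes identically to the cycle-averaged transient monitor (0.5605 vs
0.5600 m/s on the hardest cell) at a fraction of the cost; the
transient monitor remains available (`pipeline.cycle_average_monitor`)
and is what analysis/02 uses to set the default.

## Flow solver

Incompressible Newtonian blood (ρ = 1060 kg/m³, μ = 3.5 mPa·s), rigid
no-slip walls, laminar (throat Reynolds ≈ 270 at peak; the solver
refuses configurations approaching 2000).

Finite-volume discretization on the body-fitted grid with collocated
variables and SIMPLE pressure–velocity coupling:

* momentum: implicit first-order upwind convection plus a deferred
  second-order-upwind correction from Green-Gauss cell gradients;
  central diffusion with over-relaxed non-orthogonal correction;
  backward-Euler time stepping at Δt = 0.01 s over a T = 1 s cycle;
* continuity: pressure-correction equation assembled from Rhie–Chow
  momentum-interpolated face fluxes (suppresses collocated-grid
  checkerboarding); Dirichlet p′ = 0 on the outlet;
* under-relaxation 0.7 (velocity) / 0.3 (pressure); both linear systems
  are pentadiagonal and solved directly with LAPACK's banded LU, so an
  outer iteration costs a few milliseconds;
* outer iterations run until the scaled momentum and continuity
  residuals fall below 1e-3.  The residuals here are normalized by
  absolute coefficient/flux sums with no per-step renormalization, so
  1e-3 is a ~2.5-order drop within each step; tightening to 1e-5
  changes the cycle-averaged third-segment velocity by less than one
  part in 10⁶ on the hardest cell while doubling wall time.  After the
  final (direct) pressure solve of a step, the corrected face fluxes
  conserve mass to solver precision, which is why the inlet/outlet flux
  audit sits at round-off even at this tolerance.

Two cycles are simulated from a quiescent start (u = 0, p = outlet
datum) and only the second is analyzed; the cycle-to-cycle change of
the monitored metric is below 1%.  Initializing the pressure at the
outlet datum makes pressure-datum invariance hold to round-off exactly
(the whole iteration history shifts by the constant).

**Inlet waveform.**  The study uses a one-harmonic surrogate of a
generic cardiac cycle, U(t) = U0(1 + 0.5·sin(2πt/T − π/2)) with U0 =
0.2 m/s: minimum at t = 0, peak at t = T/2, cycle mean U0, always
positive.  The inlet profile is the fully developed parabola
1.5·U(t)(1−η²); the outlet pressure is a constant datum (with rigid
walls and incompressibility the outlet pressure *level* cannot affect
velocity or WSS — the datum-invariance property is tested).  Absolute
velocity/WSS magnitudes of any particular clinical waveform are
therefore not reproduced; pre/post ratios are the study's output.

**Verification.**  Steady plane Poiseuille (velocity L∞ < 2%, wall
shear 6μU/H = 1.4 Pa within 3%), oscillatory Womersley channel flow at
α ≈ 2 (< 5% of peak amplitude), mass-flux audits (steady < 1e-6,
pulsatile < 1e-3 relative), grid-convergent error decay, determinism
(bit-identical reruns), and exact invariants (WSS ⊥ n; pressure-datum
invariance) — all in the test suite.

## Metrics

WSS is the tangential projection of the wall traction,
wss = τ_t − (τ_t·n)n with τ_t = σ·n, σ = −pI + μ(∇u + ∇uᵀ).  At a
no-slip wall the velocity gradient reduces to the wall-normal
derivative, evaluated one-sidedly by a quadratic through the wall value
and the two nearest cell rows.  The projection removes the pressure
part exactly, so |wss| is pressure-datum invariant by construction.

Per model, velocity is the area-weighted mean speed over all cells of
the third segment (shoulders included; the post-stent region is the
straightened third segment's axial range), and WSS is the
arc-length-weighted mean |wss| over both walls of the same segment —
the averaging volume of "the stenosed section" is not uniquely defined
by the protocol, and segment-wide averaging is the choice least
sensitive to where the flow detaches.  Both are reported at the three
phase snapshots (waveform minimum t = 0, peak t = T/2, mid-deceleration
t = 3T/4, snapped to saved steps) and as the Δt-weighted cycle mean.
Reduction = 100·(pre − post)/pre; an increase reports as a negative
reduction.  The decomposition: stenosis-related variation per group =
reduction(0.70) − reduction(0.40); tortuosity-attributable variation
per stenosis level = max − min across the three groups.

## What the synthetic inputs do and do not emulate

The generator produces the study's *inputs*: the 24 parametric
geometries, the pulsatile waveform, and closed-form fields (Poiseuille,
Womersley, uniform) for metric unit tests.  It does not emulate
patient-specific anatomy, 3-D secondary (Dean) flows, stent struts,
wall compliance, non-Newtonian rheology, or measured coronary flow
waveforms.  Passing tests therefore demonstrate the *mechanistic
ranking* — reductions grow with stenosis severity and depend only
weakly on tortuosity — not clinical magnitudes.

## Numerical edge cases and tie-breaks

* A constant waveform degenerates the three phase snapshots into one;
  this warns rather than fails.
* Offset walls are rejected whenever h ≥ local radius of curvature;
  arcs with radius ≤ D0/2 are rejected outright.
* The mesh-independence rule raises (report attached) if no rung of the
  ladder satisfies the 5% criterion — a divergent monitor sequence is
  an error, not a silent selection.
* Interpolation weights on the graded grid are clipped to [0.05, 0.95]
  to keep face interpolation well-conditioned at the layer/core break.
* Residual divergence (growth over five consecutive outer iterations,
  or non-finite residuals) aborts with the residual trace attached.

## Known limitations

2-D planar transport (no secondary flow means tortuosity's influence is
likely *under*-stated relative to a 3-D tube); first-order time
stepping at CFL ≈ 1–5 smooths intra-cycle extrema (cycle averages are
the robust output); the idealized waveform fixes the flow split between
phases; reductions are insensitive to the outer tolerance but the
phase-resolved values carry the discretization error of the coarse
study mesh (~1–4% by the refinement sweep).
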