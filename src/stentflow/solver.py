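"""Transient incompressible flow in planar channel geometries.

Finite-volume discretization on the body-fitted structured grid with
collocated variables and SIMPLE pressure-velocity coupling:

* momentum: implicit first-order upwind convection with a deferred
  second-order-upwind correction, central diffusion with over-relaxed
  non-orthogonal correction, implicit first-order (backward Euler) time
  stepping, under-relaxed outer iterations;
* continuity: pressure-correction equation built from Rhie-Chow
  momentum-interpolated face fluxes (suppresses collocated-grid pressure
  checkerboarding);
* boundaries: prescribed velocity profile at the inlet, fixed pressure
  with zero-gradient velocity at the outlet, rigid no-slip walls.

The linear systems are pentadiagonal in lexicographic cell ordering and
are solved directly with LAPACK's banded LU, which keeps a full cardiac
cycle at study resolution to a few seconds.  The solver contains no
source of randomness: identical inputs give bit-identical fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import solve_banded

from .mesh import StructuredGrid

__all__ = [
    "FluidProperties",
    "SolverConfig",
    "Waveform",
    "FieldSeries",
    "SolverDivergenceError",
    "inlet_profile",
    "simulate",
    "solve_steady",
    "womersley_reference",
    "mass_flux_audit",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FluidProperties:
    """Incompressible Newtonian blood analog (SI units)."""

    density: float = 1060.0       # kg/m^3
    viscosity: float = 3.5e-3     # Pa s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity / self.density


@dataclass(frozen=True)
class SolverConfig:
    """Time stepping and SIMPLE iteration controls."""

    dt: float = 0.01              # s
    period: float = 1.0           # s, cardiac cycle
    n_cycles: int = 2             # first cycle(s) discarded as startup
    analyzed_cycle: int | None = None   # default: last
    relax_u: float = 0.7
    relax_p: float = 0.3
    tolerance: float = 1.0e-3     # scaled outer-iteration residual
    max_outer: int = 200

    def __post_init__(self) -> None:
        n = self.period / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("time step must divide the cycle period")
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")
        for a in (self.relax_u, self.relax_p):
            if not 0 < a <= 1:
                raise ValueError("relaxation factors must lie in (0, 1]")

    @property
    def steps_per_cycle(self) -> int:
        return int(round(self.period / self.dt))


@dataclass(frozen=True)
class Waveform:
    """Periodic inlet mean velocity and outlet pressure.

    ``mean_velocity(t)`` must be positive for all t; ``markers`` names the
    phase instants used by the metrics module (minimum, peak,
    intermediate).  ``profile`` optionally overrides the cross-channel
    inlet shape: profile(t, eta) with eta in [-1, 1]; the default is the
    fully developed parabola ``1.5 U(t) (1 - eta^2)``.
    """

    period: float
    mean_velocity: Callable[[np.ndarray], np.ndarray]
    outlet_pressure: Callable[[float], float] = lambda t: 0.0
    markers: dict = field(default_factory=dict)
    profile: Callable | None = None

    def velocity_profile(self, t: float, eta: np.ndarray) -> np.ndarray:
        if self.profile is not None:
            return self.profile(t, eta)
        return 1.5 * float(self.mean_velocity(t)) * (1.0 - eta**2)


def inlet_profile(t: float, waveform: Waveform, width: float,
                  y: np.ndarray | None = None):
    """Cross-channel inlet velocity, parabolic with mean exactly U(t).

    ``y`` is measured from the channel axis (|y| <= width/2).  Returns the
    profile values at ``y``, or a callable u(y) when ``y`` is None.
    """
    if width <= 0:
        raise ValueError("channel width must be positive")

    def u(yy):
        eta = 2.0 * np.asarray(yy, float) / width
        return waveform.velocity_profile(t, eta)

    return u if y is None else u(y)


class SolverDivergenceError(RuntimeError):
    def __init__(self, message: str, residual_trace):
        super().__init__(message)
        self.residual_trace = residual_trace


@dataclass
class FieldSeries:
    """Cell-centered fields over the analyzed cycle."""

    grid: StructuredGrid
    fvm: "_FVMesh"
    times: np.ndarray            # (nt,)
    u: np.ndarray                # (nt, ni, nj) velocity x
    v: np.ndarray                # (nt, ni, nj) velocity y
    p: np.ndarray                # (nt, ni, nj) pressure
    inlet_flux: np.ndarray       # (nt,) volumetric, into domain (m^2/s per unit depth)
    outlet_flux: np.ndarray      # (nt,) volumetric, out of domain
    continuity_residual: np.ndarray   # (nt,) scaled
    dt: float
    period: float
    waveform: Waveform | None
    fluid: FluidProperties

    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


# ---------------------------------------------------------------------------
# finite-volume mesh metrics


class _FVMesh:
    """Geometric quantities of the structured grid used by the solver."""

    def __init__(self, grid: StructuredGrid):
        self.grid = grid
        X = grid.nodes
        self.ni, self.nj = grid.ni, grid.nj
        self.V = grid.cell_areas()
        # true polygon centroids
        a, b, c, d = X[:-1, :-1], X[1:, :-1], X[1:, 1:], X[:-1, 1:]
        self.C = self._quad_centroid(a, b, c, d)
        # i-faces: edge from node (i,j) to (i,j+1); normal points +i
        e = X[:, 1:, :] - X[:, :-1, :]
        self.Si = np.stack([e[..., 1], -e[..., 0]], axis=-1)   # (ni+1, nj, 2)
        self.fci = 0.5 * (X[:, 1:, :] + X[:, :-1, :])
        # j-faces: edge from node (i,j) to (i+1,j); normal points +j
        e = X[1:, :, :] - X[:-1, :, :]
        self.Sj = np.stack([-e[..., 1], e[..., 0]], axis=-1)   # (ni, nj+1, 2)
        self.fcj = 0.5 * (X[1:, :, :] + X[:-1, :, :])

        # interior i-faces (index 1..ni-1): P = (i-1, :), N = (i, :)
        d_i = self.C[1:] - self.C[:-1]                          # (ni-1, nj, 2)
        Sif = self.Si[1:-1]
        SdotD = np.einsum("...k,...k", Sif, d_i)
        self.gdiff_i = np.einsum("...k,...k", Sif, Sif) / SdotD
        self.d_i = d_i
        self.t_i = Sif - self.gdiff_i[..., None] * d_i          # non-orth part
        # interpolation weight of N at interior i-faces
        to_f = self.fci[1:-1] - self.C[:-1]
        self.wN_i = np.clip(np.einsum("...k,...k", to_f, d_i)
                            / np.einsum("...k,...k", d_i, d_i), 0.05, 0.95)
        self.rP_i = self.fci[1:-1] - self.C[:-1]   # face centroid - upwind P
        self.rN_i = self.fci[1:-1] - self.C[1:]

        # interior j-faces (index 1..nj-1): P = (:, j-1), N = (:, j)
        d_j = self.C[:, 1:] - self.C[:, :-1]
        Sjf = self.Sj[:, 1:-1]
        SdotD = np.einsum("...k,...k", Sjf, d_j)
        self.gdiff_j = np.einsum("...k,...k", Sjf, Sjf) / SdotD
        self.d_j = d_j
        self.t_j = Sjf - self.gdiff_j[..., None] * d_j
        to_f = self.fcj[:, 1:-1] - self.C[:, :-1]
        self.wN_j = np.clip(np.einsum("...k,...k", to_f, d_j)
                            / np.einsum("...k,...k", d_j, d_j), 0.05, 0.95)
        self.rP_j = self.fcj[:, 1:-1] - self.C[:, :-1]
        self.rN_j = self.fcj[:, 1:-1] - self.C[:, 1:]

        # boundary face geometry (vector cell center -> face centroid)
        def bface(S_out, fc, Ccells):
            db = fc - Ccells
            gd = np.einsum("...k,...k", S_out, S_out) / np.einsum(
                "...k,...k", S_out, db)
            return db, gd

        self.db_in, self.gdiff_in = bface(-self.Si[0], self.fci[0], self.C[0])
        self.db_out, self.gdiff_out = bface(self.Si[-1], self.fci[-1], self.C[-1])
        self.db_lo, self.gdiff_lo = bface(-self.Sj[:, 0], self.fcj[:, 0],
                                          self.C[:, 0])
        self.db_hi, self.gdiff_hi = bface(self.Sj[:, -1], self.fcj[:, -1],
                                          self.C[:, -1])
        # normalized cross-channel coordinate of inlet face centroids
        g = grid
        n0 = (g.nodes[0, -1] - g.nodes[0, 0])
        n0 = n0 / np.linalg.norm(n0)
        mid = 0.5 * (g.nodes[0, 0] + g.nodes[0, -1])
        self.eta_in = ((self.fci[0] - mid) @ n0) / g.h[0]
        self.inlet_dir = np.array([g.nodes[0, -1, 1] - g.nodes[0, 0, 1],
                                   g.nodes[0, 0, 0] - g.nodes[0, -1, 0]])
        self.inlet_dir /= np.linalg.norm(self.inlet_dir)

    @staticmethod
    def _quad_centroid(a, b, c, d):
        def tri(p, q, r):
            area = 0.5 * ((q[..., 0] - p[..., 0]) * (r[..., 1] - p[..., 1])
                          - (q[..., 1] - p[..., 1]) * (r[..., 0] - p[..., 0]))
            return area, (p + q + r) / 3.0
        a1, c1 = tri(a, b, c)
        a2, c2 = tri(a, c, d)
        tot = a1 + a2
        return (a1[..., None] * c1 + a2[..., None] * c2) / tot[..., None]

    # face interpolation ---------------------------------------------------
    def interp_i(self, phi):
        return (1.0 - self.wN_i) * phi[:-1] + self.wN_i * phi[1:]

    def interp_j(self, phi):
        return (1.0 - self.wN_j) * phi[:, :-1] + self.wN_j * phi[:, 1:]

    def interp_i_vec(self, vec):
        return ((1.0 - self.wN_i)[..., None] * vec[:-1]
                + self.wN_i[..., None] * vec[1:])

    def interp_j_vec(self, vec):
        return ((1.0 - self.wN_j)[..., None] * vec[:, :-1]
                + self.wN_j[..., None] * vec[:, 1:])

    def gradient(self, phi, fi, fj):
        """Green-Gauss cell gradient from full face-value arrays."""
        gx = (fi[1:] * self.Si[1:, :, 0] - fi[:-1] * self.Si[:-1, :, 0]
              + fj[:, 1:] * self.Sj[:, 1:, 0] - fj[:, :-1] * self.Sj[:, :-1, 0])
        gy = (fi[1:] * self.Si[1:, :, 1] - fi[:-1] * self.Si[:-1, :, 1]
              + fj[:, 1:] * self.Sj[:, 1:, 1] - fj[:, :-1] * self.Sj[:, :-1, 1])
        return np.stack([gx, gy], axis=-1) / self.V[..., None]


# ---------------------------------------------------------------------------
# banded linear algebra


def _solve_penta(aP, aW, aE, aS, aN, rhs, nj):
    """Direct solve of the 5-point system in lexicographic order (j fastest)."""
    n = aP.size
    ab = np.zeros((2 * nj + 1, n))
    ab[nj] = aP.ravel()
    ab[nj - 1, 1:] = aN.ravel()[:-1]
    ab[nj + 1, :-1] = aS.ravel()[1:]
    ab[0, nj:] = aE.ravel()[:-nj]
    ab[2 * nj, :-nj] = aW.ravel()[nj:]
    b = rhs.reshape(n, -1)
    x = solve_banded((nj, nj), ab, b, overwrite_ab=True, overwrite_b=False)
    return x


# ---------------------------------------------------------------------------
# the SIMPLE engine


class _SimpleState:
    """Mutable solver state: fields, face fluxes, lagged gradients."""

    def __init__(self, fvm: _FVMesh, fluid: FluidProperties, p0: float):
        ni, nj = fvm.ni, fvm.nj
        self.u = np.zeros((ni, nj))
        self.v = np.zeros((ni, nj))
        self.p = np.full((ni, nj), p0)
        self.mi = np.zeros((ni + 1, nj))
        self.mj = np.zeros((ni, nj + 1))
        self.grad_p = np.zeros((ni, nj, 2))


def _face_values(fvm, phi, inlet_vals, outlet_vals, wall_val):
    """Full face-value arrays for a scalar with Dirichlet-ish boundaries."""
    fi = np.empty((fvm.ni + 1, fvm.nj))
    fi[1:-1] = fvm.interp_i(phi)
    fi[0] = inlet_vals
    fi[-1] = outlet_vals
    fj = np.empty((fvm.ni, fvm.nj + 1))
    fj[:, 1:-1] = fvm.interp_j(phi)
    fj[:, 0] = wall_val if np.ndim(wall_val) else np.full(fvm.ni, wall_val)
    fj[:, -1] = wall_val if np.ndim(wall_val) else np.full(fvm.ni, wall_val)
    return fi, fj


def _pressure_gradient(fvm, p, grad_prev, p_out):
    """Green-Gauss pressure gradient with extrapolated boundary values."""
    p_in = p[0] + np.einsum("jk,jk->j", grad_prev[0], fvm.db_in)
    p_lo = p[:, 0] + np.einsum("ik,ik->i", grad_prev[:, 0], fvm.db_lo)
    p_hi = p[:, -1] + np.einsum("ik,ik->i", grad_prev[:, -1], fvm.db_hi)
    fi = np.empty((fvm.ni + 1, fvm.nj))
    fi[1:-1] = fvm.interp_i(p)
    fi[0] = p_in
    fi[-1] = p_out
    fj = np.empty((fvm.ni, fvm.nj + 1))
    fj[:, 1:-1] = fvm.interp_j(p)
    fj[:, 0] = p_lo
    fj[:, -1] = p_hi
    return fvm.gradient(p, fi, fj)


def _outer_iteration(fvm, st, fluid, mu, dt_coef, u_old, v_old, ub_vec,
                     mi_inlet, p_out, relax_u, relax_p):
    """One SIMPLE outer iteration; returns scaled residuals (Ru, Rv, Rc)."""
    ni, nj = fvm.ni, fvm.nj
    rho = fluid.density

    # -- gradients of u, v (zero at walls, BC at inlet, zero-grad at outlet)
    fi_u, fj_u = _face_values(fvm, st.u, ub_vec[:, 0], st.u[-1], 0.0)
    fi_v, fj_v = _face_values(fvm, st.v, ub_vec[:, 1], st.v[-1], 0.0)
    grad_u = fvm.gradient(st.u, fi_u, fj_u)
    grad_v = fvm.gradient(st.v, fi_v, fj_v)
    st.grad_p = _pressure_gradient(fvm, st.p, st.grad_p, p_out)

    # -- assemble momentum coefficients ------------------------------------
    aP = np.full((ni, nj), dt_coef)
    aW = np.zeros((ni, nj))
    aE = np.zeros((ni, nj))
    aS = np.zeros((ni, nj))
    aN = np.zeros((ni, nj))
    bu = dt_coef * u_old - st.grad_p[..., 0] * fvm.V
    bv = dt_coef * v_old - st.grad_p[..., 1] * fvm.V

    def dot(a, b):
        return a[..., 0] * b[..., 0] + a[..., 1] * b[..., 1]

    def interior(m, D, t_vec, rP, rN, gu_P, gu_N, gv_P, gv_N):
        """Coefficients/sources for one family of interior faces.

        Returns (diagP_add, diagN_add, offPN, offNP, bP_u, bN_u, bP_v, bN_v).
        """
        mp = np.maximum(m, 0.0)
        mm = mp - m                       # max(-m, 0)
        diagP = D + mp
        diagN = D + mm
        offPN = -diagN
        offNP = -diagP
        # deferred second-order upwind correction
        up_is_P = m >= 0
        corr_u = m * np.where(up_is_P, dot(gu_P, rP), dot(gu_N, rN))
        corr_v = m * np.where(up_is_P, dot(gv_P, rP), dot(gv_N, rN))
        # non-orthogonal diffusion correction (over-relaxed decomposition)
        no_u = (0.5 * mu) * dot(gu_P + gu_N, t_vec)
        no_v = (0.5 * mu) * dot(gv_P + gv_N, t_vec)
        bP_u = no_u - corr_u
        bP_v = no_v - corr_v
        return diagP, diagN, offPN, offNP, bP_u, -bP_u, bP_v, -bP_v

    # interior i-faces
    (dP, dN, oPN, oNP, bPu, bNu, bPv, bNv) = interior(
        st.mi[1:-1], mu * fvm.gdiff_i, fvm.t_i, fvm.rP_i, fvm.rN_i,
        grad_u[:-1], grad_u[1:], grad_v[:-1], grad_v[1:])
    aP[:-1] += dP
    aP[1:] += dN
    aE[:-1] += oPN
    aW[1:] += oNP
    bu[:-1] += bPu
    bu[1:] += bNu
    bv[:-1] += bPv
    bv[1:] += bNv

    # interior j-faces
    (dP, dN, oPN, oNP, bPu, bNu, bPv, bNv) = interior(
        st.mj[:, 1:-1], mu * fvm.gdiff_j, fvm.t_j, fvm.rP_j, fvm.rN_j,
        grad_u[:, :-1], grad_u[:, 1:], grad_v[:, :-1], grad_v[:, 1:])
    aP[:, :-1] += dP
    aP[:, 1:] += dN
    aN[:, :-1] += oPN
    aS[:, 1:] += oNP
    bu[:, :-1] += bPu
    bu[:, 1:] += bNu
    bv[:, :-1] += bPv
    bv[:, 1:] += bNv

    # inlet boundary: known velocity, known (negative outward) flux
    Db = mu * fvm.gdiff_in
    aP[0] += Db                       # inflow convection is explicit via ub
    bu[0] += Db * ub_vec[:, 0] + mi_inlet * ub_vec[:, 0]
    bv[0] += Db * ub_vec[:, 1] + mi_inlet * ub_vec[:, 1]

    # outlet boundary: zero-gradient velocity, upwind outflow
    m_out = st.mi[-1]
    aP[-1] += np.maximum(m_out, 0.0)

    # walls: no-slip, zero flux
    aP[:, 0] += mu * fvm.gdiff_lo
    aP[:, -1] += mu * fvm.gdiff_hi

    # -- residuals of the un-relaxed system at the current state -----------
    def matvec(phi):
        out = aP * phi
        out[:-1] += aE[:-1] * phi[1:]
        out[1:] += aW[1:] * phi[:-1]
        out[:, :-1] += aN[:, :-1] * phi[:, 1:]
        out[:, 1:] += aS[:, 1:] * phi[:, :-1]
        return out

    scale_u = (np.abs(aP * st.u).sum() + np.abs(aP * st.v).sum()
               + np.abs(bu).sum() + np.abs(bv).sum() + 1e-30)
    Ru = np.abs(bu - matvec(st.u)).sum() / scale_u
    Rv = np.abs(bv - matvec(st.v)).sum() / scale_u

    # -- under-relaxation and momentum solve -------------------------------
    aP_rel = aP / relax_u
    bu_rel = bu + (1.0 - relax_u) * aP_rel * st.u
    bv_rel = bv + (1.0 - relax_u) * aP_rel * st.v
    x = _solve_penta(aP_rel, aW, aE, aS, aN,
                     np.stack([bu_rel.ravel(), bv_rel.ravel()], axis=1), nj)
    u_star = x[:, 0].reshape(ni, nj)
    v_star = x[:, 1].reshape(ni, nj)

    dP_cell = fvm.V / aP_rel

    # -- Rhie-Chow face fluxes ---------------------------------------------
    uf = fvm.interp_i_vec(np.stack([u_star, v_star], axis=-1))
    Dhat = fvm.interp_i(dP_cell)
    gpf = fvm.interp_i_vec(st.grad_p)
    dp = st.p[1:] - st.p[:-1]
    mi = np.empty_like(st.mi)
    mi[1:-1] = rho * (dot(uf, fvm.Si[1:-1])
                      - Dhat * fvm.gdiff_i * (dp - dot(gpf, fvm.d_i)))
    mi[0] = mi_inlet           # oriented +i; inlet inflow has u_b . S > 0
    # outlet: zero-gradient velocity + pressure-difference response
    mi[-1] = rho * (u_star[-1] * fvm.Si[-1, :, 0] + v_star[-1] * fvm.Si[-1, :, 1]
                    - dP_cell[-1] * fvm.gdiff_out
                    * (p_out - st.p[-1]
                       - np.einsum("jk,jk->j", st.grad_p[-1], fvm.db_out)))

    vf = fvm.interp_j_vec(np.stack([u_star, v_star], axis=-1))
    Dhat_j = fvm.interp_j(dP_cell)
    gpf_j = fvm.interp_j_vec(st.grad_p)
    dp_j = st.p[:, 1:] - st.p[:, :-1]
    mj = np.zeros_like(st.mj)
    mj[:, 1:-1] = rho * (dot(vf, fvm.Sj[:, 1:-1])
                         - Dhat_j * fvm.gdiff_j * (dp_j - dot(gpf_j, fvm.d_j)))

    # -- pressure correction ------------------------------------------------
    api = rho * Dhat * fvm.gdiff_i                 # interior i-faces
    apj = rho * Dhat_j * fvm.gdiff_j
    ab_out = rho * dP_cell[-1] * fvm.gdiff_out     # outlet Dirichlet p' = 0

    cP = np.zeros((ni, nj))
    cW = np.zeros((ni, nj))
    cE = np.zeros((ni, nj))
    cS = np.zeros((ni, nj))
    cN = np.zeros((ni, nj))
    cP[:-1] += api
    cP[1:] += api
    cE[:-1] -= api
    cW[1:] -= api
    cP[:, :-1] += apj
    cP[:, 1:] += apj
    cN[:, :-1] -= apj
    cS[:, 1:] -= apj
    cP[-1] += ab_out

    imbalance = (mi[1:] - mi[:-1] + mj[:, 1:] - mj[:, :-1])
    flux_scale = np.abs(mi_inlet).sum() + 1e-30
    Rc = np.abs(imbalance).sum() / flux_scale

    pp = _solve_penta(cP, cW, cE, cS, cN, -imbalance.ravel(), nj)
    pp = pp[:, 0].reshape(ni, nj)

    # -- corrections ---------------------------------------------------------
    st.p = st.p + relax_p * pp
    mi[1:-1] += api * (pp[:-1] - pp[1:])
    mj[:, 1:-1] += apj * (pp[:, :-1] - pp[:, 1:])
    mi[-1] += ab_out * pp[-1]
    st.mi, st.mj = mi, mj

    # cell-velocity correction from the p' gradient (p' = 0 on outlet faces)
    fi = np.empty((ni + 1, nj))
    fi[1:-1] = fvm.interp_i(pp)
    fi[0] = pp[0]
    fi[-1] = 0.0
    fj = np.empty((ni, nj + 1))
    fj[:, 1:-1] = fvm.interp_j(pp)
    fj[:, 0] = pp[:, 0]
    fj[:, -1] = pp[:, -1]
    grad_pp = fvm.gradient(pp, fi, fj)
    st.u = u_star - dP_cell * grad_pp[..., 0]
    st.v = v_star - dP_cell * grad_pp[..., 1]

    return Ru, Rv, Rc


def _run_outers(fvm, st, fluid, cfg, dt_coef, u_old, v_old, ub_vec, mi_inlet,
                p_out, max_outer, tol, context=""):
    trace = []
    for it in range(max_outer):
        Ru, Rv, Rc = _outer_iteration(
            fvm, st, fluid, fluid.viscosity, dt_coef, u_old, v_old,
            ub_vec, mi_inlet, p_out, cfg.relax_u, cfg.relax_p)
        trace.append((Ru, Rv, Rc))
        worst = max(Ru, Rv, Rc)
        if not np.isfinite(worst) or worst > 1e8:
            raise SolverDivergenceError(
                f"residual divergence {context} (iteration {it})", trace)
        if it >= 5 and all(
                max(a) > 10.0 * max(trace[it - 5]) for a in trace[it - 4:]):
            raise SolverDivergenceError(
                f"residual growth over 5 consecutive iterations {context}",
                trace)
        if worst < tol:
            break
    return trace


def _inlet_state(fvm, waveform, t):
    prof = waveform.velocity_profile(t, fvm.eta_in)
    ub_vec = prof[:, None] * fvm.inlet_dir[None, :]
    # mass inflow per inlet face (positive into the domain)
    mi_inlet = np.einsum("jk,jk->j", ub_vec, fvm.Si[0])
    return ub_vec, mi_inlet


def simulate(grid: StructuredGrid, fluid: FluidProperties, cfg: SolverConfig,
             waveform: Waveform) -> FieldSeries:
    """Transient SIMPLE solution; returns fields of the analyzed cycle only.

    Raises if the configuration leaves the laminar regime the method
    assumes (throat Reynolds number >= 2000), or on residual divergence.
    """
    fvm = _FVMesh(grid)
    tt = np.linspace(0.0, waveform.period, 512, endpoint=False)
    u_max = float(np.max(waveform.mean_velocity(tt)))
    width = 2.0 * float(grid.h[0])
    re_throat = fluid.density * u_max * width / fluid.viscosity
    if re_throat >= 2000:
        raise ValueError(
            f"throat Reynolds number {re_throat:.0f} outside laminar regime")
    if np.any(waveform.mean_velocity(tt) <= 0):
        raise ValueError("inlet waveform must be positive over the cycle")

    rho = fluid.density
    st = _SimpleState(fvm, fluid, p0=float(waveform.outlet_pressure(0.0)))
    spc = cfg.steps_per_cycle
    n_steps = spc * cfg.n_cycles
    analyzed = cfg.analyzed_cycle if cfg.analyzed_cycle is not None \
        else cfg.n_cycles - 1
    first_saved = analyzed * spc

    nt = spc
    ni, nj = fvm.ni, fvm.nj
    out = FieldSeries(
        grid=grid, fvm=fvm,
        times=np.empty(nt), u=np.empty((nt, ni, nj)), v=np.empty((nt, ni, nj)),
        p=np.empty((nt, ni, nj)), inlet_flux=np.empty(nt),
        outlet_flux=np.empty(nt), continuity_residual=np.empty(nt),
        dt=cfg.dt, period=cfg.period, waveform=waveform, fluid=fluid)

    dt_coef = rho * fvm.V / cfg.dt
    cfl_warned = False
    for n in range(1, n_steps + 1):
        t = n * cfg.dt
        ub_vec, mi_inlet_vol = _inlet_state(fvm, waveform, t)
        mi_inlet = rho * mi_inlet_vol
        p_out = float(waveform.outlet_pressure(t))
        u_old, v_old = st.u.copy(), st.v.copy()
        trace = _run_outers(fvm, st, fluid, cfg, dt_coef, u_old, v_old,
                            ub_vec, mi_inlet, p_out,
                            cfg.max_outer, cfg.tolerance,
                            context=f"at t={t:.3f}s")
        if not cfl_warned:
            speed = np.hypot(st.u, st.v).max()
            cfl = speed * cfg.dt / grid.config.axial_spacing
            if cfl > 1:
                log.info("max convective CFL %.1f > 1 (implicit stepping)", cfl)
                cfl_warned = True
        k = n - 1 - first_saved
        if 0 <= k < nt:
            out.times[k] = t
            out.u[k] = st.u
            out.v[k] = st.v
            out.p[k] = st.p
            out.inlet_flux[k] = mi_inlet.sum() / rho
            out.outlet_flux[k] = st.mi[-1].sum() / rho
            out.continuity_residual[k] = trace[-1][2]
    return out


def solve_steady(grid: StructuredGrid, fluid: FluidProperties,
                 waveform: Waveform, cfg: SolverConfig | None = None,
                 t: float = 0.0, tolerance: float = 1.0e-7,
                 max_outer: int = 2000) -> FieldSeries:
    """Steady SIMPLE solution with the inlet frozen at waveform time ``t``.

    Used by the analytic verification oracles (Poiseuille); returned as a
    single-snapshot FieldSeries.
    """
    cfg = cfg or SolverConfig()
    fvm = _FVMesh(grid)
    rho = fluid.density
    st = _SimpleState(fvm, fluid, p0=float(waveform.outlet_pressure(t)))
    ub_vec, mi_inlet_vol = _inlet_state(fvm, waveform, t)
    mi_inlet = rho * mi_inlet_vol
    p_out = float(waveform.outlet_pressure(t))
    zeros = np.zeros_like(st.u)
    trace = _run_outers(fvm, st, fluid, cfg, 0.0, zeros, zeros, ub_vec,
                        mi_inlet, p_out, max_outer, tolerance,
                        context="(steady)")
    ni, nj = fvm.ni, fvm.nj
    return FieldSeries(
        grid=grid, fvm=fvm, times=np.array([t]),
        u=st.u[None], v=st.v[None], p=st.p[None],
        inlet_flux=np.array([mi_inlet.sum() / rho]),
        outlet_flux=np.array([st.mi[-1].sum() / rho]),
        continuity_residual=np.array([trace[-1][2]]),
        dt=cfg.dt, period=cfg.period, waveform=waveform, fluid=fluid)


# ---------------------------------------------------------------------------
# analytic references and audits


def womersley_reference(omega: float, half_width: float,
                        fluid: FluidProperties, grad_amplitude: float):
    """Closed-form oscillatory plane-channel flow.

    Pressure gradient dp/dx = -G cos(omega t); returns u(y, t) with
    no-slip at y = +-half_width.  The omega -> 0 limit is the
    quasi-steady Poiseuille profile G (h^2 - y^2) / (2 mu).
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    nu = fluid.kinematic_viscosity
    lam = np.sqrt(1j * omega / nu)
    h = half_width
    G = grad_amplitude

    def u(y, t):
        y = np.asarray(y, float)
        amp = (G / (1j * omega * fluid.density)) * (
            1.0 - np.cosh(lam * y) / np.cosh(lam * h))
        return np.real(amp * np.exp(1j * omega * np.asarray(t)))

    return u


def mass_flux_audit(series: FieldSeries):
    """Per-step inlet/outlet volumetric flux and relative mismatch."""
    import pandas as pd

    if series.times.size == 0:
        raise ValueError("empty field series")
    qin = series.inlet_flux
    qout = series.outlet_flux
    denom = np.maximum(np.abs(qin), 1e-300)
    mismatch = np.where((qin == 0) & (qout == 0), 0.0,
                        np.abs(qin - qout) / denom)
    return pd.DataFrame({
        "time": series.times,
        "inlet_flux": qin,
        "outlet_flux": qout,
        "rel_mismatch": mismatch,
    })
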