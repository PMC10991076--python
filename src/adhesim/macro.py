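"""Macroscopic 1D solvers: myopic diffusion with non-local adhesion.

The parabolic model for the cell density u(t, x) on (0, L) reads

    (a+1) du/dt = c1 d/dx( D(x) du/dx )
                  + d/dx( u ( theta c1 D'(x) - chi A_r u ) ),

with c1 = 1/(2a+1) * d/(d+2) (= 1/9 for a = d = 1), no-flux boundary
conditions, and the non-local adhesion velocity A_r u evaluated with the
density extended by zero outside the domain.  The drift theta c1 D' is the
extra advection produced by splitting the myopic diffusion operator
div(div(D u)) into divergence form; theta = 0 switches to ordinary
(non-myopic) Fickian diffusion with the same coefficient.

Time stepping follows an outer-splitting scheme: on each window of length
``dt_outer`` the adhesion field (and, in CAM mode, the equilibrium bound
fraction) is frozen at the window's initial density and interpolated
linearly between grid nodes; the resulting *linear* advection-diffusion
problem is advanced over the window with an implicit (trapezoidal)
method-of-lines integrator on a fixed inner mesh of ``inner_substeps``
sub-intervals.  The spatial operator is a conservative finite-volume stencil
(half cells at the boundary nodes), so the finite-volume mass is preserved
to round-off at every step.

Hyperbolic-scaling variants are provided as well: a pure conservative
transport equation (a+1) du/dt + d/(d+1) d/dx(E u) = 0 with first-order
upwinding, and the first-order-corrected equation which adds the myopic
diffusion, an E-E cross term with prefactor d^2/((a+1)^2 (d+1)^2), and the
adhesion flux, all scaled by the correction parameter epsilon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional

import numpy as np
from scipy.linalg import solve_banded

from .kernels import DensityField1D, ForceLaw, adhesion_grid_1d
from . import cam as cam_mod

__all__ = [
    "MacroConfig",
    "Kymograph",
    "rhs_parabolic",
    "step_outer",
    "solve_ibvp",
    "solve_ibvp_cam",
    "solve_hyperbolic",
]


@dataclass
class MacroConfig:
    """Configuration of a macroscopic run (defaults follow the 1D study setup)."""

    L: float = 6.0
    T: float = 25.0
    h: float = 0.01
    dt_outer: float = 0.01
    inner_substeps: int = 41
    a: float = 1.0
    d: int = 1
    law: ForceLaw = dc_field(default_factory=ForceLaw.constant)
    chi0: float = 0.5
    D0: float = 3.0
    delta: float = 0.0
    D_field: np.ndarray | None = None  # overrides D0 + delta * x when given
    E_field: np.ndarray | float = 0.0
    theta: int = 1
    mode: str = "parabolic"  # parabolic | parabolic_cam | hyperbolic | cte
    epsilon: float = 1.0
    kinetics: cam_mod.BindingKinetics | None = None
    S: float | Callable = 0.0
    u0: DensityField1D | None = None
    advection: str = "centered"  # face density averaging: centered | upwind
    stencil: str = "right"  # adhesion Riemann-sum convention: right | left

    def __post_init__(self) -> None:
        if self.h <= 0 or self.dt_outer <= 0:
            raise ValueError("h and dt_outer must be positive")
        if abs(self.T / self.dt_outer - round(self.T / self.dt_outer)) > 1e-9:
            raise ValueError("T must be a multiple of dt_outer")
        if self.inner_substeps < 1:
            raise ValueError("inner_substeps must be >= 1")
        if self.mode not in ("parabolic", "parabolic_cam", "hyperbolic", "cte"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.advection not in ("centered", "upwind"):
            raise ValueError("advection must be 'centered' or 'upwind'")
        if self.u0 is None:
            self.u0 = DensityField1D.uniform(5.0, L=self.L, h=self.h)
        if self.u0.h != self.h or abs(self.u0.L - self.L) > 1e-9:
            raise ValueError("u0 grid does not match (L, h)")
        if np.any(self.D_values() < 0):
            raise ValueError("diffusion coefficient D[q] must be non-negative")

    @property
    def n(self) -> int:
        return int(round(self.L / self.h)) + 1

    @property
    def x(self) -> np.ndarray:
        return self.h * np.arange(self.n)

    @property
    def c1(self) -> float:
        """Diffusion prefactor 1/(2a+1) * d/(d+2) of the parabolic limit."""
        return (1.0 / (2.0 * self.a + 1.0)) * (self.d / (self.d + 2.0))

    def D_values(self) -> np.ndarray:
        if self.D_field is not None:
            D = np.asarray(self.D_field, dtype=float)
            if D.shape != (self.n,):
                raise ValueError("D_field must be a nodal array")
            return D
        return self.D0 + self.delta * self.x

    def E_values(self) -> np.ndarray:
        E = np.asarray(self.E_field, dtype=float)
        if E.ndim == 0:
            return np.full(self.n, float(E))
        if E.shape != (self.n,):
            raise ValueError("E_field must be scalar or a nodal array")
        return E

    def echo(self) -> dict:
        return {
            "L": self.L, "T": self.T, "h": self.h, "dt_outer": self.dt_outer,
            "inner_substeps": self.inner_substeps, "a": self.a, "d": self.d,
            "r": self.law.r, "chi0": self.chi0, "D0": self.D0,
            "delta": self.delta, "theta": self.theta, "mode": self.mode,
            "epsilon": self.epsilon, "advection": self.advection,
        }


@dataclass
class Kymograph:
    """Time-stacked density snapshots of a run."""

    t: np.ndarray
    x: np.ndarray
    U: np.ndarray  # (n_times, n_nodes)
    mass: np.ndarray
    config: dict

    def __post_init__(self) -> None:
        if self.U.shape != (self.t.size, self.x.size):
            raise ValueError("snapshot matrix shape mismatch")
        if not np.all(np.isfinite(self.mass)):
            raise ValueError("non-finite mass encountered")

    def final(self) -> DensityField1D:
        h = float(self.x[1] - self.x[0])
        return DensityField1D(values=self.U[-1].copy(), h=h)

    def field_at(self, k: int) -> DensityField1D:
        h = float(self.x[1] - self.x[0])
        return DensityField1D(values=self.U[k].copy(), h=h)

    def write_text(self, path) -> None:
        """First row = x grid (with a nan placeholder), first column = t."""
        top = np.concatenate([[np.nan], self.x])
        body = np.column_stack([self.t, self.U])
        np.savetxt(path, np.vstack([top, body]), delimiter="\t")

    @classmethod
    def read_text(cls, path, config: dict | None = None) -> "Kymograph":
        raw = np.loadtxt(path, delimiter="\t")
        x = raw[0, 1:]
        t = raw[1:, 0]
        U = raw[1:, 1:]
        h = float(x[1] - x[0])
        w = np.full(x.size, h)
        w[0] = w[-1] = h / 2
        return cls(t=t, x=x, U=U, mass=U @ w, config=config or {})


# ---------------------------------------------------------------------------
# spatial operator assembly
# ---------------------------------------------------------------------------

def _cell_widths(n: int, h: float) -> np.ndarray:
    w = np.full(n, h)
    w[0] = w[-1] = h / 2.0
    return w


def _face_coefficients(cfg: MacroConfig, adh_nodes: np.ndarray, eps_scale: float,
                       include_E: bool):
    """Per-face (cL, cR) such that the total flux at face j is cL u_j + cR u_{j+1}."""
    n, h = cfg.n, cfg.h
    c1 = cfg.c1
    D = cfg.D_values()
    D_f = 0.5 * (D[:-1] + D[1:])
    dD_f = (D[1:] - D[:-1]) / h
    adh_f = 0.5 * (adh_nodes[:-1] + adh_nodes[1:])  # linear interp at midpoints
    adv_f = eps_scale * (cfg.theta * c1 * dD_f - adh_f)

    cL = eps_scale * (-c1 * D_f / h)
    cR = eps_scale * (c1 * D_f / h)
    if cfg.advection == "centered":
        cL = cL + 0.5 * adv_f
        cR = cR + 0.5 * adv_f
    else:
        # mass velocity is -adv/(a+1): positive -> take the left (donor) node
        take_left = adv_f <= 0.0
        cL = cL + np.where(take_left, adv_f, 0.0)
        cR = cR + np.where(~take_left, adv_f, 0.0)

    if include_E:
        E = cfg.E_values()
        E_f = 0.5 * (E[:-1] + E[1:])
        hyp = cfg.d / (cfg.d + 1.0)
        # transport flux -hyp * E u, upwinded by the sign of the wave speed E
        take_left = E_f >= 0.0
        cL = cL + np.where(take_left, -hyp * E_f, 0.0)
        cR = cR + np.where(~take_left, -hyp * E_f, 0.0)
        # first-order cross term: flux -eps * coef * E d/dx(u E)
        coef = cfg.epsilon * cfg.d**2 / ((cfg.a + 1.0) ** 2 * (cfg.d + 1.0) ** 2)
        cL = cL + coef * E_f * E[:-1] / h
        cR = cR - coef * E_f * E[1:] / h
    return cL, cR


def _assemble_tridiag(cfg: MacroConfig, adh_nodes: np.ndarray,
                      eps_scale: float = 1.0, include_E: bool = False):
    """Tridiagonal generator A with du/dt = A u (no-flux at both ends)."""
    n, h = cfg.n, cfg.h
    cL, cR = _face_coefficients(cfg, adh_nodes, eps_scale, include_E)
    w = _cell_widths(n, h) * (cfg.a + 1.0)
    lower = np.zeros(n)   # A[m, m-1] stored at index m
    diag = np.zeros(n)
    upper = np.zeros(n)   # A[m, m+1] stored at index m
    # face j contributes +flux to node j, -flux to node j+1
    diag[:-1] += cL / w[:-1]
    upper[:-1] += cR / w[:-1]
    diag[1:] -= cR / w[1:]
    lower[1:] -= cL / w[1:]
    return lower, diag, upper


def _tridiag_matvec(lower, diag, upper, u):
    out = diag * u
    out[:-1] += upper[:-1] * u[1:]
    out[1:] += lower[1:] * u[:-1]
    return out


def _cn_advance(lower, diag, upper, u, dt_total, substeps):
    """Trapezoidal (Crank-Nicolson-type) advance of du/dt = A u over dt_total."""
    dt = dt_total / substeps
    n = u.size
    ab = np.zeros((3, n))
    ab[0, 1:] = -0.5 * dt * upper[:-1]
    ab[1, :] = 1.0 - 0.5 * dt * diag
    ab[2, :-1] = -0.5 * dt * lower[1:]
    for _ in range(substeps):
        rhs = u + 0.5 * dt * _tridiag_matvec(lower, diag, upper, u)
        u = solve_banded((1, 1), ab, rhs)
    return u


def _frozen_adhesion(u: DensityField1D, cfg: MacroConfig) -> np.ndarray:
    """chi * A_r u on the nodes (the advective adhesion velocity)."""
    s = adhesion_grid_1d(u, cfg.law, stencil=cfg.stencil)
    return cfg.chi0 * s / (cfg.law.r * cfg.law.ball_volume)


def rhs_parabolic(u: DensityField1D, frozen_adh: np.ndarray, cfg: MacroConfig) -> np.ndarray:
    """Semi-discrete right-hand side of the parabolic equation for frozen adhesion.

    ``frozen_adh`` is the nodal adhesion velocity chi * A_r u.  Returns du/dt
    on the nodes for the conservative finite-volume stencil with no-flux
    boundaries.
    """
    lower, diag, upper = _assemble_tridiag(cfg, np.asarray(frozen_adh, dtype=float))
    return _tridiag_matvec(lower, diag, upper, u.values)


def step_outer(u_k: DensityField1D, cfg: MacroConfig,
               mu1_over_u: np.ndarray | None = None,
               include_E: bool = False, eps_scale: float = 1.0) -> DensityField1D:
    """One outer splitting window: freeze adhesion at u_k, advance implicitly.

    In CAM mode ``mu1_over_u`` is the frozen equilibrium bound fraction per
    cell; it multiplies the adhesion velocity (the flux term chi mu1 A_r u).
    """
    adh = _frozen_adhesion(u_k, cfg)
    if mu1_over_u is not None:
        adh = adh * mu1_over_u
    lower, diag, upper = _assemble_tridiag(cfg, adh, eps_scale=eps_scale,
                                           include_E=include_E)
    new_vals = _cn_advance(lower, diag, upper, u_k.values.copy(),
                           cfg.dt_outer, cfg.inner_substeps)
    return u_k.copy_with(new_vals)


def _record(kt, kU, km, t, u: DensityField1D):
    kt.append(t)
    kU.append(u.values.copy())
    km.append(u.mass())


def solve_ibvp(cfg: MacroConfig, snapshot_stride: int = 1) -> Kymograph:
    """Integrate the parabolic adhesion/myopic-diffusion problem to time T."""
    if cfg.mode != "parabolic":
        raise ValueError("solve_ibvp handles mode='parabolic'")
    n_outer = int(round(cfg.T / cfg.dt_outer))
    u = cfg.u0
    kt, kU, km = [], [], []
    _record(kt, kU, km, 0.0, u)
    for k in range(n_outer):
        u = step_outer(u, cfg)
        if (k + 1) % snapshot_stride == 0 or k == n_outer - 1:
            _record(kt, kU, km, (k + 1) * cfg.dt_outer, u)
    return Kymograph(t=np.asarray(kt), x=cfg.x, U=np.asarray(kU),
                     mass=np.asarray(km), config=cfg.echo())


def solve_ibvp_cam(cfg: MacroConfig, snapshot_stride: int = 1,
                   picard_tol: float = 1e-10) -> tuple[Kymograph, Kymograph]:
    """Integrate the CAM-coupled parabolic system to time T.

    Per outer window the bound-CAM moment mu1 is recomputed from the current
    density by the fixed-point solver, the bound fraction mu1/u is frozen as
    the adhesion prefactor (so the flux advection term is chi mu1 A_r u), and
    the window is advanced as in :func:`step_outer`.  The chemical field S is
    taken static in time, which keeps the binding kernel matrices fixed
    across the run.
    """
    if cfg.mode != "parabolic_cam":
        raise ValueError("solve_ibvp_cam handles mode='parabolic_cam'")
    if cfg.kinetics is None:
        raise ValueError("CAM mode requires binding kinetics")
    n_outer = int(round(cfg.T / cfg.dt_outer))
    u = cfg.u0
    banded = cam_mod.build_g_banded(u, cfg.S, cfg.kinetics)
    kt, kU, km = [], [], []
    mt, mU, mm = [], [], []
    mu1 = cam_mod.solve_bound_fraction(u, cfg.S, cfg.kinetics,
                                       tol=picard_tol, banded=banded)
    _record(kt, kU, km, 0.0, u)
    _record(mt, mU, mm, 0.0, mu1)
    for k in range(n_outer):
        try:
            mu1 = cam_mod.solve_bound_fraction(u, cfg.S, cfg.kinetics,
                                               tol=picard_tol, banded=banded)
        except (RuntimeError, ArithmeticError) as exc:
            raise RuntimeError(f"CAM solver failed at outer step {k}: {exc}") from exc
        with np.errstate(divide="ignore", invalid="ignore"):
            ybar = np.where(u.values > 1e-300, mu1.values / u.values, 0.0)
        u = step_outer(u, cfg, mu1_over_u=ybar)
        if (k + 1) % snapshot_stride == 0 or k == n_outer - 1:
            _record(kt, kU, km, (k + 1) * cfg.dt_outer, u)
            # re-equilibrate so the recorded moment matches the recorded density
            mu1_snap = cam_mod.solve_bound_fraction(u, cfg.S, cfg.kinetics,
                                                    tol=picard_tol, banded=banded)
            _record(mt, mU, mm, (k + 1) * cfg.dt_outer, mu1_snap)
    ky_u = Kymograph(t=np.asarray(kt), x=cfg.x, U=np.asarray(kU),
                     mass=np.asarray(km), config=cfg.echo())
    ky_m = Kymograph(t=np.asarray(mt), x=cfg.x, U=np.asarray(mU),
                     mass=np.asarray(mm), config=cfg.echo())
    return ky_u, ky_m


def solve_hyperbolic(cfg: MacroConfig, snapshot_stride: int = 1) -> Kymograph:
    """Hyperbolic-scaling solvers.

    mode='cte': pure conservative transport (a+1) du/dt + d/(d+1) (E u)_x = 0
    with explicit first-order upwinding on the outer time mesh.
    mode='hyperbolic': adds the O(epsilon) corrections (myopic diffusion,
    E-E cross term, adhesion flux) and advances with the implicit splitting
    scheme, the transport term upwinded inside the operator.
    """
    if cfg.mode not in ("cte", "hyperbolic"):
        raise ValueError("solve_hyperbolic handles mode in {'cte', 'hyperbolic'}")
    E = cfg.E_values()
    speed = (cfg.d / (cfg.d + 1.0)) * np.max(np.abs(E)) / (cfg.a + 1.0)
    cfl = speed * cfg.dt_outer / cfg.h
    if cfg.mode == "cte" and cfl > 1.0 + 1e-12:
        raise ValueError(f"CFL condition violated (number {cfl:.3f} > 1)")
    n_outer = int(round(cfg.T / cfg.dt_outer))
    u = cfg.u0
    kt, kU, km = [], [], []
    _record(kt, kU, km, 0.0, u)
    if cfg.mode == "cte":
        hyp = cfg.d / (cfg.d + 1.0)
        E_f = 0.5 * (E[:-1] + E[1:])
        w = _cell_widths(cfg.n, cfg.h) * (cfg.a + 1.0)
        vals = u.values.copy()
        for k in range(n_outer):
            donor = np.where(E_f >= 0, vals[:-1], vals[1:])
            flux = -hyp * E_f * donor  # total face flux; du/dt = d(flux)/dx/(a+1)
            div = np.zeros(cfg.n)
            div[:-1] += flux / w[:-1]
            div[1:] -= flux / w[1:]
            vals = vals + cfg.dt_outer * div
            if (k + 1) % snapshot_stride == 0 or k == n_outer - 1:
                _record(kt, kU, km, (k + 1) * cfg.dt_outer, u.copy_with(vals))
        return Kymograph(t=np.asarray(kt), x=cfg.x, U=np.asarray(kU),
                         mass=np.asarray(km), config=cfg.echo())
    # first-order corrected hyperbolic model via the implicit splitting scheme
    for k in range(n_outer):
        u = step_outer(u, cfg, include_E=True, eps_scale=cfg.epsilon)
        if (k + 1) % snapshot_stride == 0 or k == n_outer - 1:
            _record(kt, kU, km, (k + 1) * cfg.dt_outer, u)
    return Kymograph(t=np.asarray(kt), x=cfg.x, U=np.asarray(kU),
                     mass=np.asarray(km), config=cfg.echo())
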