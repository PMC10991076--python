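"""Macroscopic CAM-binding machinery.

On the macroscale the fast binding/unbinding of cell adhesion molecules
(CAMs, e.g. cadherins) equilibrates instantaneously and closes onto the pair
of macroscopic moments (mu0, mu1) = (cell density, bound-CAM density).  The
equilibrium bound fraction at a point is given by the functional

    Y_r[S](mu0, mu1) = G+_r[S](mu0 - mu1) / ( G+_r[S](mu0 - mu1) + G-_r[S] mu1 ),

where G+-_r[S] are non-local integral operators with kernels
``k+-(S((x+x')/2), |x-x'|) / |B_r|`` supported on pair distances below the
sensing radius, and the bound-CAM density solves the non-linear integral
equation

    mu1 = mu0 * Y_r[S](mu0, mu1),

handled here by a damped Picard iteration.  In the local-kernel limit
(binding possible only at zero distance, with rates K+-(S)) the equation
collapses to the closed form mu1 = sqrt(K+)/(sqrt(K+) + sqrt(K-)) * mu0.

The module also provides the mesoscopic reconstruction profile: the
equilibrium velocity distribution of the kinetic model factorises as
``mu0 * q(v) * xi1(|v|)`` with the speed profile ``xi1`` obtained from the
characteristics of the drag-turning balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np

from .kernels import DensityField1D, unit_ball_volume

__all__ = [
    "BindingKinetics",
    "MomentPair",
    "kinetics_example",
    "g_pair",
    "apply_g",
    "build_g_banded",
    "y_star",
    "solve_bound_fraction",
    "bound_fraction_local",
    "xi1",
    "reconstruct_meso",
]


@dataclass
class BindingKinetics:
    """Binding/unbinding rate constants k+-(S, rho) with cutoff at rho = r.

    ``kplus``/``kminus`` are callables of (chemical concentration, pair
    distance), vectorised over numpy arrays, identically zero for distances
    at or beyond the sensing radius.  ``cap`` bounds the unbinding rate: the
    standard example family blows up as the distance approaches r, while the
    analysis requires essential boundedness, so values above ``cap`` are
    clipped.
    """

    kplus: Callable
    kminus: Callable
    r: float
    d: int = 1
    cap: float = 1e6

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("sensing radius must be positive")

    @property
    def ball_volume(self) -> float:
        return unit_ball_volume(self.d, self.r)

    def rates(self, S, rho):
        """(k+, k-) with the distance cutoff and the k- ceiling applied."""
        S = np.asarray(S, dtype=float)
        rho = np.asarray(rho, dtype=float)
        inside = rho < self.r
        kp = np.where(inside, self.kplus(S, np.minimum(rho, self.r)), 0.0)
        km = np.where(inside, self.kminus(S, np.minimum(rho, self.r)), 0.0)
        km = np.minimum(km, self.cap)
        kp = np.asarray(kp, dtype=float)
        km = np.asarray(km, dtype=float)
        if kp.ndim == 0:
            return float(kp), float(km)
        return kp, km


def kinetics_example(
    r: float = 1.0,
    Kplus: float | Callable = 1.0,
    Kminus: float | Callable = 1.0,
    a_plus: float = 1.0,
    b_plus: float = 1.0,
    a_minus: float = 1.0,
    b_minus: float = 1.0,
    d: int = 1,
    cap: float = 1e6,
) -> BindingKinetics:
    """Separable rate family k+- = K+-(S) * phi+-(rho).

    The distance profiles are ``phi+ = (r^b+ - rho^b+)^{a+}`` (binding fades
    with distance) and ``phi- = (r^b- - rho^b-)^{-a-}`` (unbinding speeds up
    sharply as the pair distance approaches the sensing radius); both vanish
    for rho >= r.  K+ is meant to be non-decreasing and K- non-increasing in
    the chemical concentration S, although this is not enforced.
    """
    Kp = Kplus if callable(Kplus) else (lambda S, _v=float(Kplus): np.full_like(np.asarray(S, dtype=float), _v))
    Km = Kminus if callable(Kminus) else (lambda S, _v=float(Kminus): np.full_like(np.asarray(S, dtype=float), _v))

    def kplus(S, rho):
        base = np.maximum(r**b_plus - np.asarray(rho, dtype=float) ** b_plus, 0.0)
        return Kp(S) * base**a_plus

    def kminus(S, rho):
        base = np.maximum(r**b_minus - np.asarray(rho, dtype=float) ** b_minus, 0.0)
        with np.errstate(divide="ignore"):
            prof = np.where(base > 0, base ** (-a_minus), np.inf)
        return Km(S) * prof

    return BindingKinetics(kplus=kplus, kminus=kminus, r=r, d=d, cap=cap)


@dataclass
class MomentPair:
    """Zeroth and first bound-CAM moments of the cell distribution plus the chemical field."""

    mu0: DensityField1D
    mu1: DensityField1D
    S: float | Callable | np.ndarray = 0.0

    def __post_init__(self) -> None:
        if self.mu0.n != self.mu1.n or self.mu0.h != self.mu1.h:
            raise ValueError("mu0 and mu1 must share a grid")
        if np.any(self.mu1.values < -1e-12) or np.any(
            self.mu1.values > self.mu0.values + 1e-12
        ):
            raise ValueError("moments must satisfy 0 <= mu1 <= mu0 nodewise")


def g_pair(S_mid: float, dist: float, kin: BindingKinetics) -> tuple[float, float]:
    """Mass-action pair kernels (G+, G-) = k+-(S_mid, dist) / |B_r|."""
    if dist < 0:
        raise ValueError("distance must be non-negative")
    kp, km = kin.rates(S_mid, dist)
    inv = 1.0 / kin.ball_volume
    return kp * inv, km * inv


def _S_at(S, t_x: np.ndarray) -> np.ndarray:
    """Evaluate the chemical field at positions ``t_x`` (array of x)."""
    if callable(S):
        return np.asarray(S(t_x), dtype=float)
    arr = np.asarray(S, dtype=float)
    if arr.ndim == 0:
        return np.full(t_x.shape, float(arr))
    raise ValueError(
        "gridded chemical fields must be wrapped in an interpolating callable "
        "(midpoints fall off the grid)"
    )


def build_g_banded(grid: DensityField1D, S, kin: BindingKinetics):
    """Banded kernel matrices for the non-local operators G+-_r[S] on the grid.

    Returns (offsets l, Gp, Gm) where Gp/Gm have shape (n, 2 l_r + 1) holding
    ``G+-(S((x_m + x_{m+l})/2), |l| h)`` for offsets ``l = -l_r .. l_r``
    (kernel values at distance exactly r are zero by the cutoff).  The field
    operator is then the banded matvec h * sum_l G[m, l] u[m+l] with zero
    extension of u outside [0, L].
    """
    h = grid.h
    l_r = int(round(kin.r / h))
    ls = np.arange(-l_r, l_r + 1)
    x = grid.x
    mids = 0.5 * (x[:, None] + (x[:, None] + ls[None, :] * h))  # (n, 2l_r+1)
    dists = np.abs(ls[None, :] * h) * np.ones((grid.n, 1))
    S_mid = _S_at(S, mids)
    kp, km = kin.rates(S_mid, dists)
    inv = 1.0 / kin.ball_volume
    return ls, kp * inv, km * inv


def _banded_matvec(ls: np.ndarray, G: np.ndarray, u: np.ndarray, h: float) -> np.ndarray:
    l_r = int(ls.max())
    padded = np.concatenate([np.zeros(l_r), u, np.zeros(l_r)])
    n = u.size
    out = np.zeros(n)
    for k, l in enumerate(ls):
        out += G[:, k] * padded[l_r + l : l_r + l + n]
    return h * out


def apply_g(
    mu: DensityField1D,
    S,
    kin: BindingKinetics,
    sign: str,
    banded=None,
) -> np.ndarray:
    """Field operator (G+-_r[S] mu)(x) by a Riemann sum over the band |x - x'| < r.

    ``sign`` is "+" or "-".  The density is extended by zero outside [0, L].
    A precomputed band from :func:`build_g_banded` may be passed to avoid
    rebuilding the kernel.
    """
    if sign not in ("+", "-"):
        raise ValueError("sign must be '+' or '-'")
    if banded is None:
        banded = build_g_banded(mu, S, kin)
    ls, Gp, Gm = banded
    G = Gp if sign == "+" else Gm
    return _banded_matvec(ls, G, mu.values, mu.h)


def y_star(mp: MomentPair, kin: BindingKinetics, banded=None) -> np.ndarray:
    """Equilibrium bound fraction Y_r[S](mu0, mu1) nodewise.

    Raises if the denominator G+(mu0 - mu1) + G-(mu1) vanishes at any node
    (the well-definedness condition of the equilibrium).
    """
    if banded is None:
        banded = build_g_banded(mp.mu0, mp.S, kin)
    ls, Gp, Gm = banded
    free = np.clip(mp.mu0.values - mp.mu1.values, 0.0, None)
    num = _banded_matvec(ls, Gp, free, mp.mu0.h)
    den = num + _banded_matvec(ls, Gm, mp.mu1.values, mp.mu0.h)
    bad = np.nonzero(den <= 0.0)[0]
    if bad.size:
        raise ArithmeticError(
            f"degenerate binding state: zero denominator at node {int(bad[0])} "
            f"(x = {bad[0] * mp.mu0.h:g})"
        )
    out = num / den
    return np.clip(out, 0.0, 1.0)


def solve_bound_fraction(
    mu0: DensityField1D,
    S,
    kin: BindingKinetics,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    omega: float = 0.5,
    banded=None,
) -> DensityField1D:
    """Solve mu1 = mu0 * Y_r[S](mu0, mu1) by damped Picard iteration.

    Starts from mu1 = mu0 / 2 and iterates
    ``mu1 <- (1 - omega) mu1 + omega mu0 Y_r(mu0, mu1)`` until the residual
    sup-norm drops below ``tol``.  The iterate is clipped to [0, mu0] every
    sweep, so the output always satisfies the moment ordering.
    """
    if np.any(mu0.values < 0):
        raise ValueError("mu0 must be non-negative")
    if not np.any(mu0.values > 0):
        raise ValueError("mu0 must not vanish identically")
    if banded is None:
        banded = build_g_banded(mu0, S, kin)
    ls, Gp, Gm = banded
    alive = mu0.values > 0.0
    mu1 = 0.5 * mu0.values
    for _ in range(max_iter):
        free = np.clip(mu0.values - mu1, 0.0, None)
        num = _banded_matvec(ls, Gp, free, mu0.h)
        den = num + _banded_matvec(ls, Gm, mu1, mu0.h)
        # nodes with no cells trivially satisfy mu1 = mu0 = 0 whatever the
        # (possibly empty) sensing ball says; the equilibrium fraction is
        # only required where cells are present
        bad = np.nonzero(alive & (den <= 0.0))[0]
        if bad.size:
            raise ArithmeticError(
                f"degenerate binding state: zero denominator at node "
                f"{int(bad[0])} (x = {bad[0] * mu0.h:g})"
            )
        Y = np.zeros_like(mu1)
        ok = den > 0.0
        Y[ok] = np.clip(num[ok] / den[ok], 0.0, 1.0)
        target = mu0.values * Y
        residual = float(np.max(np.abs(mu1 - target)))
        mu1 = np.clip((1.0 - omega) * mu1 + omega * target, 0.0, mu0.values)
        if residual <= tol:
            return mu0.copy_with(mu1)
    raise RuntimeError(
        f"bound-fraction fixed point did not converge in {max_iter} iterations "
        f"(last residual {residual:.3e})"
    )


def bound_fraction_local(Kplus, Kminus, mu0):
    """Closed-form bound-CAM density for strictly local binding kernels.

    mu1 = sqrt(K+) / (sqrt(K+) + sqrt(K-)) * mu0, elementwise over fields.
    """
    Kp = np.asarray(Kplus, dtype=float)
    Km = np.asarray(Kminus, dtype=float)
    if np.any(Kp < 0) or np.any(Km < 0):
        raise ValueError("rates must be non-negative")
    if np.any(Kp + Km <= 0):
        raise ArithmeticError("both rates vanish at a node; bound fraction undefined")
    mu0_vals = mu0.values if isinstance(mu0, DensityField1D) else np.asarray(mu0, dtype=float)
    frac = np.sqrt(Kp) / (np.sqrt(Kp) + np.sqrt(Km))
    out = frac * mu0_vals
    if isinstance(mu0, DensityField1D):
        return mu0.copy_with(out)
    return out


def xi1(v, a: float, d: int = 1) -> float:
    """Equilibrium speed profile of the drag-turning balance.

    xi1(v) = d/(da - 1) (|v|^{-d + 1/a} - 1) for a != 1/d, and
    -(d/a) ln|v| in the resonant case a = 1/d.  Singular at v = 0.
    """
    speed = float(np.linalg.norm(np.atleast_1d(np.asarray(v, dtype=float))))
    if speed == 0.0:
        raise ValueError("xi1 is singular at v = 0")
    if speed > 1.0 + 1e-12:
        raise ValueError("velocities live in the closed unit ball")
    if abs(a - 1.0 / d) < 1e-14:
        return -(d / a) * math.log(speed)
    return d / (d * a - 1.0) * (speed ** (-d + 1.0 / a) - 1.0)


def reconstruct_meso(mu0_point: float, q_at_x, a: float, d: int = 1) -> Callable:
    """Factorised equilibrium velocity profile v -> mu0 * q(v) * xi1(v).

    For d = 1, ``q_at_x`` is the direction pair (q_plus, q_minus) at the
    reconstruction point.  The profile integrates to ``mu0_point`` over the
    velocity ball.
    """
    if d != 1:
        raise NotImplementedError("mesoscopic reconstruction implemented for d = 1")
    qp, qm = (float(q_at_x[0]), float(q_at_x[1]))

    def profile(v: float) -> float:
        if v == 0.0:
            raise ValueError("profile singular at v = 0")
        q = qp if v > 0 else qm
        return mu0_point * q * xi1(v, a, d)

    return profile
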