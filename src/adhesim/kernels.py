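"""Adhesion potential, non-local adhesion operator, and fiber-distribution moments.

The non-local adhesion machinery is built around a radially symmetric
potential supported on the sensing ball ``B_r``,

    H_r(x) = 1/(r |B_r|) * int_{min(|x|, r)}^{r} F(s) ds,

whose gradient supplies the pairwise attraction force between cells.  The
adhesion operator ``A_r u = grad(H_r) * u`` (convolution in space) averages a
cell density against the directional kernel ``(xi/|xi|) F(|xi|)`` and is the
velocity field that drives aggregation in the macroscopic equations.

Two evaluation paths are provided: a slow adaptive-quadrature pointwise
operator (:func:`adhesion_point`, used as an oracle) and the production grid
discretisation (:func:`adhesion_grid_1d`) which reproduces, index bound by
index bound, the right-Riemann-sum / cross-correlation stencil used to solve
the 1D aggregation problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import integrate


__all__ = [
    "ForceLaw",
    "DensityField1D",
    "FiberDistribution",
    "FiberMoments",
    "unit_ball_volume",
    "potential_value",
    "potential_gradient",
    "adhesion_point",
    "adhesion_grid_1d",
    "adhesion_stencil",
    "ring_operator",
    "fiber_moments",
    "velocity_bound_ok",
]


def unit_ball_volume(d: int, rho: float) -> float:
    """Volume of the ball of radius ``rho`` in ``d`` dimensions (2*rho for d=1)."""
    if d == 1:
        return 2.0 * rho
    if d == 2:
        return math.pi * rho * rho
    if d == 3:
        return 4.0 * math.pi * rho**3 / 3.0
    return math.pi ** (d / 2.0) * rho**d / math.gamma(d / 2.0 + 1.0)


@dataclass(frozen=True)
class ForceLaw:
    """Distance profile of the adhesion force inside the sensing ball.

    Parameters
    ----------
    F : callable
        Non-negative force profile on ``[0, r]`` (dimensionless).
    r : float
        Sensing radius (> 0, space units).
    d : int
        Spatial dimension.
    constant_f : float, optional
        If the profile is a constant, its value.  Enables closed forms and a
        fast counting path in the particle simulation; purely an optimisation
        hint, results agree with the generic path.
    """

    F: Callable[[float], float]
    r: float
    d: int = 1
    constant_f: float | None = None

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("sensing radius r must be positive")
        if self.d < 1:
            raise ValueError("spatial dimension d must be >= 1")
        # spot-check non-negativity of F on a sample grid
        s = np.linspace(0.0, self.r, 33)
        vals = np.asarray([self.F(float(si)) for si in s], dtype=float)
        if np.any(vals < 0):
            raise ValueError("force profile F must be non-negative on [0, r]")

    @property
    def ball_volume(self) -> float:
        """|B_r| in d dimensions (= 2r for d = 1)."""
        return unit_ball_volume(self.d, self.r)

    @property
    def norm(self) -> float:
        """The kernel normalisation 1/(r |B_r|)."""
        return 1.0 / (self.r * self.ball_volume)

    def sup_F(self) -> float:
        if self.constant_f is not None:
            return self.constant_f
        s = np.linspace(0.0, self.r, 2049)
        return float(max(self.F(float(si)) for si in s))

    @classmethod
    def constant(cls, value: float = 1.0, r: float = 1.0, d: int = 1) -> "ForceLaw":
        """Force law with constant profile ``F == value`` (the standard study choice)."""
        if value < 0:
            raise ValueError("constant force value must be non-negative")
        return cls(F=lambda s, _v=value: _v, r=r, d=d, constant_f=value)


@dataclass
class DensityField1D:
    """Cell density sampled on the uniform grid ``x_m = m h`` covering [0, L].

    Nodes include both endpoints, so a domain of length ``L`` with spacing
    ``h`` carries ``round(L/h) + 1`` values (601 for L=6, h=0.01).  Mass is
    accounted with finite-volume weights: interior nodes own cells of width
    ``h``, the two boundary nodes own half cells.
    """

    values: np.ndarray
    h: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("values must be a 1D array with at least two nodes")
        if self.h <= 0:
            raise ValueError("grid spacing h must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def L(self) -> float:
        return self.h * (self.n - 1)

    @property
    def x(self) -> np.ndarray:
        return self.h * np.arange(self.n)

    def mass(self) -> float:
        """Finite-volume (trapezoid-weight) total mass h * sum with half-weight ends."""
        w = np.full(self.n, self.h)
        w[0] = w[-1] = self.h / 2.0
        return float(np.dot(w, self.values))

    def copy_with(self, values: np.ndarray) -> "DensityField1D":
        return DensityField1D(values=np.asarray(values, dtype=float), h=self.h)

    @classmethod
    def uniform(cls, level: float, L: float = 6.0, h: float = 0.01) -> "DensityField1D":
        n = int(round(L / h)) + 1
        return cls(values=np.full(n, float(level)), h=h)


# ---------------------------------------------------------------------------
# potential and its gradient
# ---------------------------------------------------------------------------

def potential_value(x, law: ForceLaw) -> float:
    """Adhesion potential H_r at offset ``x`` (scalar or d-vector)."""
    xa = np.atleast_1d(np.asarray(x, dtype=float))
    s0 = min(float(np.linalg.norm(xa)), law.r)
    if s0 >= law.r:
        return 0.0
    if law.constant_f is not None:
        integral = law.constant_f * (law.r - s0)
    else:
        integral, _ = integrate.quad(law.F, s0, law.r, epsabs=1e-12, limit=200)
    return law.norm * integral


def potential_gradient(x, law: ForceLaw):
    """Gradient of H_r at offset ``x``.

    Zero outside the closed ball and at the origin (the convention
    ``sign(0) = 0``); on the sphere ``|x| = r`` the one-sided value based on
    ``F(r)`` is used, matching the discrete stencil which includes its right
    endpoint.  Returns a scalar for d = 1, an array of shape (d,) otherwise.
    """
    xa = np.atleast_1d(np.asarray(x, dtype=float))
    nrm = float(np.linalg.norm(xa))
    if nrm == 0.0 or nrm > law.r:
        g = np.zeros_like(xa)
    else:
        g = -law.norm * (xa / nrm) * law.F(nrm)
    if law.d == 1 and np.isscalar(x) or (np.ndim(x) == 0):
        return float(g[0])
    return g


# ---------------------------------------------------------------------------
# adhesion operator: pointwise quadrature (oracle) and grid stencil (production)
# ---------------------------------------------------------------------------

def adhesion_point(u: Callable, x, law: ForceLaw, tol: float = 1e-10):
    """A_r u(x) by adaptive quadrature (slow oracle path).

    ``u`` is a callable density, zero-extended by the caller where it has no
    support.  In d = 1 this is

        A_r u(x) = 1/(2 r^2) * int_{-r}^{r} u(x + xi) sign(xi) F(|xi|) dxi,

    returned as a float; in d = 2 polar quadrature over the disc is used and
    an array of shape (2,) is returned.
    """
    if law.d == 1:
        x0 = float(np.asarray(x).reshape(()))

        def integrand(xi: float) -> float:
            return u(x0 + xi) * math.copysign(1.0, xi) * law.F(abs(xi))

        left, el = integrate.quad(integrand, -law.r, 0.0, epsabs=tol, limit=400)
        right, er = integrate.quad(integrand, 0.0, law.r, epsabs=tol, limit=400)
        if el + er > 100 * tol + 1e-8:
            raise RuntimeError(
                f"adhesion quadrature did not converge (error estimate {el + er:.2e})"
            )
        return law.norm * (left + right)
    if law.d == 2:
        x0 = np.asarray(x, dtype=float).reshape(2)
        comps = []
        for k in range(2):
            def integrand(rho, th, _k=k):
                e = np.array([math.cos(th), math.sin(th)])
                return u(x0 + rho * e) * e[_k] * law.F(rho) * rho

            val, err = integrate.dblquad(
                integrand, 0.0, 2 * math.pi, 0.0, law.r, epsabs=tol * 10
            )
            comps.append(val)
        return law.norm * np.asarray(comps)
    raise NotImplementedError("pointwise adhesion quadrature implemented for d in {1, 2}")


def adhesion_stencil(law: ForceLaw, h: float, stencil: str = "right") -> np.ndarray:
    """Directional weight stencil ``w_l = sign(l) F(|l h|)``.

    ``stencil="right"`` (the production convention) uses offsets
    l = -(l_r - 1) .. l_r with l_r = round(r/h): the right-Riemann-sum
    discretisation of the adhesion integral, which includes the right
    endpoint of the sensing ball but not the left one.  The stencil is
    therefore *not* antisymmetric: on a constant field it leaves a residue
    h * u * F(r).  ``stencil="left"`` is the mirror image (offsets
    -l_r .. l_r - 1); reflection-conjugating a run with it reproduces the
    mirror of a "right" run exactly, which pins down the symmetry content of
    the scheme.
    """
    if law.r <= h:
        raise ValueError("sensing radius unresolved: r must exceed the grid spacing h")
    l_r = int(round(law.r / h))
    if stencil == "right":
        ls = np.arange(-(l_r - 1), l_r + 1)
    elif stencil == "left":
        ls = np.arange(-l_r, l_r)
    else:
        raise ValueError("stencil must be 'right' or 'left'")
    w = np.sign(ls).astype(float)
    if law.constant_f is not None:
        w *= law.constant_f
    else:
        w *= np.array([law.F(abs(l) * h) for l in ls])
    return w


def adhesion_grid_1d(u: DensityField1D, law: ForceLaw, stencil: str = "right") -> np.ndarray:
    """Right-Riemann-sum adhesion field on the grid (1D production path).

    Returns the *bare* directional integral

        s_m = h * sum_{l=a(m)}^{b(m)} u(x_{m+l}) sign(l h) F(|l h|),

    with a(m) = max(-(l_r - 1), -m), b(m) = min(l_r, M - m), i.e. the density
    is extended by zero outside [0, L].  The adhesion operator value is
    ``s_m / (r |B_r|)``; the bare sum is kept because it is the quantity the
    1D scheme interpolates and feeds into the advective flux.  Implemented as
    a discrete cross-correlation with :func:`adhesion_stencil`.
    """
    if law.d != 1:
        raise ValueError("grid adhesion field is 1D only")
    w = adhesion_stencil(law, u.h, stencil=stencil)
    l_r = int(round(law.r / u.h))
    if stencil == "right":
        padded = np.concatenate([np.zeros(l_r - 1), u.values, np.zeros(l_r)])
    else:
        padded = np.concatenate([np.zeros(l_r), u.values, np.zeros(l_r - 1)])
    # s_m = sum_k padded[m + k] w[k]  -> 'valid' correlation
    return u.h * np.correlate(padded, w, mode="valid")


def ring_operator(u: Callable, x, rho: float, d: int = 2, n_theta: int = 4096) -> np.ndarray:
    """Sphere-averaged directional operator int_{S_rho} u(x + xi) xi dxi.

    The measure-valued gradient of the indicator potential of the sensing
    ball; used for non-local gradient sensing in d >= 2.  Trapezoid rule on
    the circle for d = 2, product Gauss x trapezoid quadrature for d = 3.
    """
    if d < 2:
        raise ValueError("ring operator requires d >= 2 (the sphere is a point pair in 1D)")
    x0 = np.asarray(x, dtype=float).reshape(d)
    if d == 2:
        th = np.linspace(0.0, 2 * math.pi, n_theta, endpoint=False)
        e = np.stack([np.cos(th), np.sin(th)], axis=1)  # (n, 2)
        vals = np.array([u(x0 + rho * ei) for ei in e])
        # xi = rho e, line element rho dtheta
        return rho**2 * (2 * math.pi / n_theta) * (vals[:, None] * e).sum(axis=0)
    if d == 3:
        n_phi = 64
        mu, wmu = np.polynomial.legendre.leggauss(n_phi)  # mu = cos(polar)
        th = np.linspace(0.0, 2 * math.pi, 256, endpoint=False)
        out = np.zeros(3)
        for m, wm in zip(mu, wmu):
            s = math.sqrt(1 - m * m)
            e = np.stack([s * np.cos(th), s * np.sin(th), np.full_like(th, m)], axis=1)
            vals = np.array([u(x0 + rho * ei) for ei in e])
            out += wm * (2 * math.pi / th.size) * (vals[:, None] * e).sum(axis=0)
        return rho**3 * out
    raise NotImplementedError("ring operator implemented for d in {2, 3}")


# ---------------------------------------------------------------------------
# fiber orientation distribution and its moments
# ---------------------------------------------------------------------------

@dataclass
class FiberDistribution:
    """Orientational distribution ``q`` of tissue fibers over unit directions.

    Normalised so that the sum/integral over the unit sphere equals 1 (which
    makes the mean over the unit velocity ball equal 1/d).  In 1D the sphere
    is the direction pair {+1, -1} and ``q`` reduces to the pair
    ``(q_plus(x), q_minus(x))``; either scalars or nodal arrays are accepted.
    In d = 2 ``q_of_theta`` is a density on the circle.
    """

    d: int = 1
    q_plus: np.ndarray | float | None = None
    q_minus: np.ndarray | float | None = None
    q_of_theta: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.d == 1:
            if self.q_plus is None or self.q_minus is None:
                raise ValueError("d=1 fiber distribution needs (q_plus, q_minus)")
            if not callable(self.q_plus):
                self.q_plus = np.asarray(self.q_plus, dtype=float)
                self.q_minus = np.asarray(self.q_minus, dtype=float)
        elif self.q_of_theta is None:
            raise ValueError("d>=2 fiber distribution needs a circle density q_of_theta")

    @classmethod
    def isotropic_1d(cls) -> "FiberDistribution":
        return cls(d=1, q_plus=0.5, q_minus=0.5)


@dataclass
class FiberMoments:
    """First and second directional moments E[q], D[q] of a fiber distribution."""

    E: np.ndarray
    D: np.ndarray


def fiber_moments(q: FiberDistribution, tol: float = 1e-8) -> FiberMoments:
    """E[q] = int theta q(theta), D[q] = int theta theta^T q(theta) over S_1.

    For d = 1: E = q_plus - q_minus and D = q_plus + q_minus.  Raises if the
    normalisation (sum/integral over directions equals 1) is violated beyond
    ``tol``.
    """
    if q.d == 1:
        if callable(q.q_plus):
            raise ValueError("evaluate a callable fiber distribution on a grid first")
        total = np.asarray(q.q_plus + q.q_minus, dtype=float)
        if np.any(np.abs(total - 1.0) > tol):
            raise ValueError("fiber distribution not normalised: q_plus + q_minus != 1")
        return FiberMoments(
            E=np.asarray(q.q_plus - q.q_minus, dtype=float),
            D=np.asarray(q.q_plus + q.q_minus, dtype=float),
        )
    if q.d == 2:
        n = 4096
        th = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
        qs = np.array([q.q_of_theta(t) for t in th])
        dth = 2 * math.pi / n
        if abs(qs.sum() * dth - 1.0) > max(tol, 1e-6):
            raise ValueError("fiber distribution not normalised on the circle")
        e = np.stack([np.cos(th), np.sin(th)], axis=1)
        E = dth * (qs[:, None] * e).sum(axis=0)
        D = dth * np.einsum("n,ni,nj->ij", qs, e, e)
        return FiberMoments(E=E, D=D)
    raise NotImplementedError("fiber moments implemented for d in {1, 2}")


def velocity_bound_ok(law: ForceLaw, chi_sup: float, a: float) -> bool:
    """Check the speed-cap condition sup|grad H_r| * sup(chi) <= a.

    When it holds, cell speeds in the particle model never exceed the (rescaled)
    cap 1, so velocities stay inside the unit ball.
    """
    if chi_sup < 0 or a < 0:
        raise ValueError("chi_sup and a must be non-negative")
    return law.norm * chi_sup * law.sup_F() <= a
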