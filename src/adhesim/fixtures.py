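"""Deterministic, seeded generators for every input the simulators consume.

All generators are pure functions of their parameters (and seed); nothing is
downloaded or read from disk.  They produce the canonical study conditions —
a uniform density of 5 cells per unit length on (0, 6), the affine diffusion
field D0 + delta x, the separable binding-rate family — as well as generic
particle clouds and Gaussian-bump initial data for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .kernels import DensityField1D, FiberMoments, ForceLaw
from .micro import MicroParams, MicroState
from . import cam as cam_mod

__all__ = [
    "FixtureSpec",
    "make_ic",
    "make_fiber_field",
    "make_particle_cloud",
    "two_cell_attracting",
    "constant_chemical",
    "example_kinetics",
    "make",
]


@dataclass
class FixtureSpec:
    """Declarative fixture: a kind, its parameters, and a seed."""

    kind: str
    params: dict = dc_field(default_factory=dict)
    seed: int | None = None


def make_ic(
    kind: str = "uniform",
    level: float = 5.0,
    L: float = 6.0,
    h: float = 0.01,
    bumps: list | None = None,
) -> DensityField1D:
    """Initial density: ``uniform`` level, or a sum of Gaussian bumps.

    Each bump is a dict with keys center, width (std dev) and mass; bump
    fields are normalised so the stated masses are exact on the grid.
    """
    if level < 0 or L <= 0 or h <= 0:
        raise ValueError("negative or degenerate initial-condition parameters")
    n = int(round(L / h)) + 1
    x = h * np.arange(n)
    if kind == "uniform":
        return DensityField1D(values=np.full(n, float(level)), h=h)
    if kind == "gaussian_bumps":
        vals = np.zeros(n)
        for b in bumps or []:
            c, w, m = float(b["center"]), float(b["width"]), float(b["mass"])
            if w <= 0 or m < 0:
                raise ValueError("bump width must be positive and mass non-negative")
            prof = np.exp(-0.5 * ((x - c) / w) ** 2)
            f = DensityField1D(values=prof, h=h)
            pm = f.mass()
            vals += m * prof / pm if pm > 0 else 0.0
        return DensityField1D(values=vals, h=h)
    raise ValueError(f"unknown initial-condition kind {kind!r}")


def make_fiber_field(
    D0: float, delta: float, L: float = 6.0, h: float = 0.01, E: float | np.ndarray = 0.0
) -> FiberMoments:
    """Affine second-moment field D(x) = D0 + delta x with (default) zero drift moment."""
    n = int(round(L / h)) + 1
    x = h * np.arange(n)
    D = D0 + delta * x
    if np.any(D < 0):
        raise ValueError("D0 + delta x must be non-negative on [0, L]")
    E_arr = np.asarray(E, dtype=float)
    if E_arr.ndim == 0:
        E_arr = np.full(n, float(E_arr))
    return FiberMoments(E=E_arr, D=D)


def make_particle_cloud(
    n: int,
    region: tuple = (0.0, 6.0),
    speed_cap: float = 0.0,
    seed: int | None = 0,
    cam: bool = False,
    params: MicroParams | None = None,
) -> MicroState:
    """Seeded uniform particle cloud in 1D.

    Positions uniform in ``region``, velocities uniform in (-speed_cap,
    speed_cap), bound-CAM fractions uniform in (0, 1) when ``cam``.
    """
    if n < 1:
        raise ValueError("need at least one particle")
    rng = np.random.default_rng(seed)
    lo, hi = region
    x = rng.uniform(lo, hi, size=n)
    v = rng.uniform(-speed_cap, speed_cap, size=n) if speed_cap > 0 else np.zeros(n)
    y = rng.uniform(0.0, 1.0, size=n) if cam else None
    if params is None:
        params = MicroParams()
    return MicroState(t=0.0, x=x, v=v, params=params, y=y)


def two_cell_attracting(params: MicroParams | None = None) -> MicroState:
    """Two resting cells half a sensing radius apart; they attract symmetrically."""
    if params is None:
        params = MicroParams(a=1.0, chi=1.0, law=ForceLaw.constant())
    return MicroState(
        t=0.0, x=np.array([0.0, 0.5]), v=np.zeros(2), params=params
    )


def constant_chemical(level: float = 1.0):
    """Spatially constant chemical concentration field S(x) = level."""
    lvl = float(level)

    def S(x):
        return np.full(np.shape(np.asarray(x)), lvl) if np.ndim(x) else lvl

    return S


def example_kinetics(**kwargs) -> cam_mod.BindingKinetics:
    """The separable binding/unbinding rate family (thin alias)."""
    return cam_mod.kinetics_example(**kwargs)


_PRESETS = {
    "two-cell": two_cell_attracting,
}


def make(spec: FixtureSpec):
    """Build a fixture from a declarative spec (dispatch on ``spec.kind``)."""
    k = spec.kind
    if k == "uniform_ic":
        return make_ic(kind="uniform", **spec.params)
    if k == "gaussian_bumps_ic":
        return make_ic(kind="gaussian_bumps", **spec.params)
    if k == "linear_fiber_field":
        return make_fiber_field(**spec.params)
    if k == "constant_chemical":
        return constant_chemical(**spec.params)
    if k == "example41_kinetics":
        return example_kinetics(**spec.params)
    if k == "particle_cloud":
        return make_particle_cloud(seed=spec.seed, **spec.params)
    if k in _PRESETS:
        return _PRESETS[k]()
    raise ValueError(f"unknown fixture kind {k!r}")
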