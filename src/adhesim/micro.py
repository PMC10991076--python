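"""Agent-based simulation of adhesive cell motion with optional CAM binding.

Each of N point cells carries a position ``x_i``, a velocity ``v_i`` inside
the unit ball (speeds are rescaled so the physical cap is 1), and, in
CAM mode, a bound-CAM fraction ``y_i`` in [0, 1].  The deterministic dynamics
is Newtonian with Stokes drag and a mean-field pairwise adhesion force,

    dx_i/dt = v_i,
    dv_i/dt = -a v_i + chi(t, x_i) [y_i] (1/N) sum_{j != i} grad H_r(x_i - x_j),
    dy_i/dt = (1/N) sum_{j != i} [ G+ (1-y_i)(1-y_j) - G- y_i y_j ],

where the mass-action kernels G+- are the binding/unbinding rates divided by
the sensing-ball volume, evaluated at the chemical concentration at the pair
midpoint and the pair distance.  Stochastic re-orientation along tissue
fibers is realised as a velocity-jump process: unit-rate exponential waiting
times, new direction drawn from the fiber distribution, new speed uniform on
(0, 1) (the unique speed sampling consistent with a direction-only turning
kernel).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional, Sequence
import warnings

import numpy as np

from .kernels import DensityField1D, ForceLaw, velocity_bound_ok, FiberDistribution

__all__ = [
    "MicroParams",
    "MicroState",
    "Trajectory",
    "adhesion_acceleration",
    "adhesion_accelerations",
    "cam_rate",
    "cam_rates",
    "step_deterministic",
    "step_turning",
    "empirical_density",
    "simulate_micro",
]


def _as_const(f):
    if callable(f):
        return f
    val = float(f)
    return lambda t, x, _v=val: np.full(np.shape(np.atleast_1d(x))[0], _v) if np.ndim(x) else _v


@dataclass
class MicroParams:
    """Dynamic parameters shared by all cells.

    chi may be a constant or a callable ``chi(t, x)`` (vectorised over the
    particle axis); ``chi_sup`` is its supremum, needed for the speed-cap
    check.  ``kinetics`` / ``S`` switch on CAM mode.
    """

    a: float = 1.0
    chi: float | Callable = 1.0
    chi_sup: float | None = None
    law: ForceLaw = dc_field(default_factory=ForceLaw.constant)
    kinetics: object | None = None  # cam.BindingKinetics
    S: float | Callable | None = None

    def __post_init__(self) -> None:
        if self.chi_sup is None:
            if callable(self.chi):
                raise ValueError("chi_sup must be given when chi is a function")
            self.chi_sup = float(self.chi)

    def chi_at(self, t: float, x: np.ndarray) -> np.ndarray:
        if callable(self.chi):
            return np.asarray(self.chi(t, x), dtype=float)
        return np.full(x.shape[0], float(self.chi))

    def S_at(self, t: float, x: np.ndarray) -> np.ndarray:
        if self.S is None:
            raise ValueError("no chemical field configured")
        if callable(self.S):
            return np.asarray(self.S(t, x), dtype=float)
        return np.full(np.shape(x)[0] if np.ndim(x) else (), float(self.S), dtype=float)

    @property
    def cam_mode(self) -> bool:
        return self.kinetics is not None


@dataclass
class MicroState:
    """Positions, velocities and optional bound-CAM fractions of N cells.

    ``x`` and ``v`` have shape (N,) in 1D or (N, d) in general; ``y`` is None
    outside CAM mode.
    """

    t: float
    x: np.ndarray
    v: np.ndarray
    params: MicroParams
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.x.shape != self.v.shape:
            raise ValueError("x and v must have matching shapes")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != (self.N,):
                raise ValueError("y must have shape (N,)")
        if self.params.cam_mode and self.y is None:
            raise ValueError("CAM mode requires bound-CAM fractions y")

    @property
    def N(self) -> int:
        return self.x.shape[0]

    @property
    def d(self) -> int:
        return 1 if self.x.ndim == 1 else self.x.shape[1]

    def copy(self) -> "MicroState":
        return MicroState(
            t=self.t,
            x=self.x.copy(),
            v=self.v.copy(),
            params=self.params,
            y=None if self.y is None else self.y.copy(),
        )


@dataclass
class Trajectory:
    """Snapshots of a particle run plus the RNG provenance needed to replay it."""

    times: list
    states: list
    seed: int | None = None
    generator: str = "numpy.random.Generator(PCG64)"

    def __post_init__(self) -> None:
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("snapshot times must be strictly increasing")
        ns = {s.N for s in self.states}
        if len(ns) > 1:
            raise ValueError("population size must be constant across snapshots")

    def to_table(self) -> np.ndarray:
        """Long-format array with columns (t, particle id, x, v, y)."""
        rows = []
        for t, s in zip(self.times, self.states):
            y = s.y if s.y is not None else np.full(s.N, np.nan)
            x = s.x if s.x.ndim == 1 else s.x[:, 0]
            v = s.v if s.v.ndim == 1 else s.v[:, 0]
            rows.append(np.column_stack([np.full(s.N, t), np.arange(s.N), x, v, y]))
        return np.concatenate(rows, axis=0)

    def save(self, path) -> None:
        np.savetxt(
            path,
            self.to_table(),
            header="t\tid\tx\tv\ty",
            delimiter="\t",
            comments="",
        )


# ---------------------------------------------------------------------------
# forces and rates
# ---------------------------------------------------------------------------

def _pair_gradient_sum_1d(x: np.ndarray, law: ForceLaw) -> np.ndarray:
    """sum_{j != i} grad H_r(x_i - x_j) for all i, direct O(N^2), 1D."""
    diff = x[:, None] - x[None, :]  # x_i - x_j
    absd = np.abs(diff)
    with np.errstate(invalid="ignore"):
        if law.constant_f is not None:
            fvals = np.full_like(absd, law.constant_f)
        else:
            fvals = np.vectorize(law.F)(np.clip(absd, 0.0, law.r))
        g = -law.norm * np.sign(diff) * fvals
    g[absd > law.r] = 0.0
    np.fill_diagonal(g, 0.0)
    return g.sum(axis=1)


def _pair_gradient_sum_1d_constF(x: np.ndarray, law: ForceLaw) -> np.ndarray:
    """Counting shortcut for constant F in 1D (O(N log N)).

    For constant F the force on cell i is proportional to the number of
    neighbours strictly to the right within distance r (the sphere |xi| = r
    included, consistent with the grid stencil) minus those to the left.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = x.size
    # neighbours in (x_i, x_i + r]  and  [x_i - r, x_i)
    right = np.searchsorted(xs, xs + law.r, side="right") - np.searchsorted(
        xs, xs, side="right"
    )
    left = np.searchsorted(xs, xs, side="left") - np.searchsorted(
        xs, xs - law.r, side="left"
    )
    out = np.empty(n)
    out[order] = law.norm * law.constant_f * (right - left).astype(float)
    return out


def adhesion_accelerations(state: MicroState, t: float | None = None) -> np.ndarray:
    """Adhesion acceleration for every cell (vectorised)."""
    p = state.params
    t = state.t if t is None else t
    law = p.law
    if state.d == 1:
        if law.constant_f is not None:
            grad_sum = _pair_gradient_sum_1d_constF(state.x, law)
        else:
            grad_sum = _pair_gradient_sum_1d(state.x, law)
        acc = p.chi_at(t, state.x) * grad_sum / state.N
    else:
        diff = state.x[:, None, :] - state.x[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        mask = (dist > 0) & (dist <= law.r)
        fvals = np.zeros_like(dist)
        if law.constant_f is not None:
            fvals[mask] = law.constant_f
        else:
            fvals[mask] = np.vectorize(law.F)(dist[mask])
        with np.errstate(divide="ignore", invalid="ignore"):
            unit = np.where(dist[..., None] > 0, diff / dist[..., None], 0.0)
        g = -law.norm * unit * fvals[..., None]
        acc = p.chi_at(t, state.x)[:, None] * g.sum(axis=1) / state.N
    if p.cam_mode:
        acc = acc * (state.y if acc.ndim == 1 else state.y[:, None])
    return acc


def adhesion_acceleration(state: MicroState, i: int) -> float | np.ndarray:
    """Adhesion acceleration of cell ``i`` by the direct pairwise sum."""
    from .kernels import potential_gradient

    p = state.params
    xi = state.x[i]
    total = 0.0 if state.d == 1 else np.zeros(state.d)
    for j in range(state.N):
        if j == i:
            continue
        total = total + potential_gradient(xi - state.x[j], p.law)
    chi_i = float(np.atleast_1d(p.chi_at(state.t, np.atleast_1d(xi)))[0])
    pref = chi_i / state.N
    if p.cam_mode:
        pref *= state.y[i]
    return pref * total


def cam_rates(state: MicroState, t: float | None = None, y: np.ndarray | None = None) -> np.ndarray:
    """dy_i/dt for every cell by the mass-action pairwise sum (O(N^2))."""
    p = state.params
    if not p.cam_mode:
        raise ValueError("CAM kinetics not configured")
    t = state.t if t is None else t
    y = state.y if y is None else y
    kin = p.kinetics
    x = state.x if state.d == 1 else state.x
    if state.d == 1:
        diff = x[:, None] - x[None, :]
        dist = np.abs(diff)
        mid = 0.5 * (x[:, None] + x[None, :])
    else:
        diff = x[:, None, :] - x[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        mid = 0.5 * (x[:, None, :] + x[None, :, :])
    S_mid = p.S_at(t, mid.reshape(-1, *mid.shape[2:])).reshape(dist.shape) \
        if callable(p.S) else np.full(dist.shape, float(p.S))
    kp, km = kin.rates(S_mid, dist)
    inv_ball = 1.0 / kin.ball_volume
    one_m = 1.0 - y
    gain = inv_ball * kp * (one_m[:, None] * one_m[None, :])
    loss = inv_ball * km * (y[:, None] * y[None, :])
    rate = gain - loss
    np.fill_diagonal(rate, 0.0)
    return rate.sum(axis=1) / state.N


def cam_rate(state: MicroState, i: int) -> float:
    """dy_i/dt of cell ``i`` (direct pairwise sum)."""
    p = state.params
    if not p.cam_mode:
        raise ValueError("CAM kinetics not configured")
    kin = p.kinetics
    total = 0.0
    xi, yi = state.x[i], state.y[i]
    for j in range(state.N):
        if j == i:
            continue
        xj, yj = state.x[j], state.y[j]
        dist = float(np.linalg.norm(np.atleast_1d(xi - xj)))
        mid = 0.5 * (xi + xj)
        Sm = float(np.atleast_1d(p.S_at(state.t, np.atleast_1d(mid)))[0]) \
            if callable(p.S) else float(p.S)
        kp, km = kin.rates(Sm, dist)
        gp, gm = kp / kin.ball_volume, km / kin.ball_volume
        total += gp * (1 - yi) * (1 - yj) - gm * yi * yj
    return total / state.N


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

def _derivatives(state: MicroState, t: float, x, v, y):
    work = MicroState(t=t, x=x, v=v, params=state.params,
                      y=y if state.params.cam_mode else None)
    dx = v
    dv = -state.params.a * v + adhesion_accelerations(work, t=t)
    dy = cam_rates(work, t=t, y=y) if state.params.cam_mode else None
    return dx, dv, dy


def step_deterministic(state: MicroState, dt: float) -> MicroState:
    """One explicit RK4 step of the coupled (x, v, y) dynamics.

    Refuses to run if the speed-cap condition fails (velocities could then
    leave the unit ball).  Bound fractions are clipped to [0, 1] after the
    step to absorb round-off at the barrier.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = state.params
    if not velocity_bound_ok(p.law, p.chi_sup, p.a):
        raise ValueError(
            "speed-cap condition violated: sup|grad H_r| * sup(chi) > a; "
            "refusing to simulate"
        )
    t, x, v, y = state.t, state.x, state.v, state.y

    k1 = _derivatives(state, t, x, v, y)
    k2 = _derivatives(state, t + dt / 2,
                      x + dt / 2 * k1[0], v + dt / 2 * k1[1],
                      None if y is None else y + dt / 2 * k1[2])
    k3 = _derivatives(state, t + dt / 2,
                      x + dt / 2 * k2[0], v + dt / 2 * k2[1],
                      None if y is None else y + dt / 2 * k2[2])
    k4 = _derivatives(state, t + dt,
                      x + dt * k3[0], v + dt * k3[1],
                      None if y is None else y + dt * k3[2])

    xn = x + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    vn = v + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    yn = None
    if y is not None:
        yn = y + dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        if np.any(yn < -1e-12) or np.any(yn > 1 + 1e-12):
            warnings.warn("bound-CAM fraction left [0,1] beyond round-off; clipping")
        yn = np.clip(yn, 0.0, 1.0)
    return MicroState(t=t + dt, x=xn, v=vn, params=p, y=yn)


def step_turning(
    state: MicroState,
    dt: float,
    q: FiberDistribution,
    rng: np.random.Generator,
) -> MicroState:
    """Velocity-jump reorientation step (1D).

    Each cell turns with probability 1 - exp(-dt) (unit turning rate); on a
    turn the new direction is +1 with probability q_plus(x_i) and the new
    speed is uniform on (0, 1), which realises sampling from the density
    ``d q`` on the velocity ball.
    """
    if state.d != 1 or q.d != 1:
        raise ValueError("turning simulation is restricted to 1D")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = state.N
    turns = rng.random(n) < -np.expm1(-dt)
    n_turn = int(turns.sum())
    if n_turn == 0:
        out = state.copy()
        out.t = state.t + 0.0
        return out
    if callable(q.q_plus):
        qp_at = np.asarray(q.q_plus(state.x[turns]), dtype=float)
    else:
        qp = np.asarray(q.q_plus, dtype=float)
        if qp.ndim == 0 or qp.size == 1:
            qp_at = np.full(n_turn, float(qp))
        else:
            raise ValueError(
                "spatially varying q must be supplied as a callable q_plus(x)"
            )
    direction = np.where(rng.random(n_turn) < qp_at, 1.0, -1.0)
    speed = rng.random(n_turn)
    vn = state.v.copy()
    vn[turns] = direction * speed
    out = state.copy()
    out.v = vn
    return out


def empirical_density(
    state: MicroState,
    grid: DensityField1D,
    total_mass: float = 1.0,
) -> DensityField1D:
    """Histogram of positions on the grid, normalised to ``total_mass``.

    Particles are assigned to the node owning the half-open cell
    [x_m, x_{m+1}); particles outside [0, L] are dropped with a warning.
    """
    if state.d != 1:
        raise ValueError("empirical density is 1D")
    h = grid.h
    x = state.x
    inside = (x >= 0.0) & (x <= grid.L)
    if not np.all(inside):
        warnings.warn(f"{int((~inside).sum())} particles outside the grid were dropped")
        x = x[inside]
    idx = np.minimum((x / h).astype(int), grid.n - 1)
    counts = np.bincount(idx, minlength=grid.n).astype(float)
    values = counts * (total_mass / (state.N * h))
    return grid.copy_with(values)


def simulate_micro(
    initial: MicroState,
    T: float,
    dt: float,
    q: FiberDistribution | None = None,
    snapshot_every: int = 1,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Run the particle model to time T, interleaving drift and turning steps."""
    if q is not None and rng is None:
        rng = np.random.default_rng(seed)
    n_steps = int(round(T / dt))
    state = initial.copy()
    times = [state.t]
    states = [state.copy()]
    for k in range(n_steps):
        state = step_deterministic(state, dt)
        if q is not None:
            state = step_turning(state, dt, q, rng)
        if (k + 1) % snapshot_every == 0 or k == n_steps - 1:
            times.append(state.t)
            states.append(state.copy())
    return Trajectory(times=times, states=states, seed=seed)
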