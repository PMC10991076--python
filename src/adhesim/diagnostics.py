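"""Aggregate detection, mass accounting and micro-macro comparison metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import DensityField1D
from .macro import Kymograph
from .micro import Trajectory, empirical_density

__all__ = [
    "AggregateSummary",
    "total_mass",
    "detect_aggregates",
    "peak_density_ratio",
    "compare_micro_macro",
    "summary_row",
]


@dataclass
class AggregateSummary:
    """Peaks of a density profile above a threshold.

    An aggregate is a maximal contiguous run of nodes with density strictly
    above the threshold; its peak is the run's maximum node (leftmost on
    ties).  ``min_spacing`` is None when fewer than two aggregates exist.
    """

    count: int
    peak_positions: list
    peak_heights: list
    min_spacing: float | None
    threshold: float

    def __post_init__(self) -> None:
        if not (self.count == len(self.peak_positions) == len(self.peak_heights)):
            raise ValueError("inconsistent aggregate summary")
        if any(b <= a for a, b in zip(self.peak_positions, self.peak_positions[1:])):
            raise ValueError("peak positions must be strictly increasing")


def total_mass(u: DensityField1D) -> float:
    """Total mass with the finite-volume node weights (half cells at the ends)."""
    return u.mass()


def detect_aggregates(u: DensityField1D, threshold: float) -> AggregateSummary:
    """Find aggregates of ``u`` as super-threshold runs of nodes."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    above = u.values > threshold
    positions, heights = [], []
    x = u.x
    i = 0
    n = u.n
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            seg = u.values[i : j + 1]
            k = int(np.argmax(seg))  # argmax takes the leftmost maximum
            positions.append(float(x[i + k]))
            heights.append(float(seg[k]))
            i = j + 1
        else:
            i += 1
    spacing = None
    if len(positions) >= 2:
        spacing = float(np.min(np.diff(positions)))
    return AggregateSummary(
        count=len(positions),
        peak_positions=positions,
        peak_heights=heights,
        min_spacing=spacing,
        threshold=threshold,
    )


def peak_density_ratio(kA: Kymograph, kB: Kymograph) -> float:
    """Ratio of the maximal final densities of two runs on the same grid."""
    if kA.x.shape != kB.x.shape or not np.allclose(kA.x, kB.x):
        raise ValueError("kymographs live on different grids")
    return float(kA.U[-1].max() / kB.U[-1].max())


def compare_micro_macro(
    traj: Trajectory, kymo: Kymograph, total_mass: float, time_tol: float = 1e-9
) -> np.ndarray:
    """Relative L1 distance between binned particle snapshots and PDE snapshots.

    Returns an array of rows (t, error) over the snapshot times the two runs
    share.  The particle positions are binned onto the kymograph grid and
    normalised to ``total_mass`` before comparison.
    """
    h = float(kymo.x[1] - kymo.x[0])
    grid = DensityField1D(values=np.zeros(kymo.x.size), h=h)
    rows = []
    kt = np.asarray(kymo.t)
    for t, s in zip(traj.times, traj.states):
        hits = np.nonzero(np.abs(kt - t) <= time_tol)[0]
        if hits.size == 0:
            continue
        k = int(hits[0])
        emp = empirical_density(s, grid, total_mass=total_mass)
        ref = kymo.U[k]
        denom = np.sum(np.abs(ref)) * h
        err = np.sum(np.abs(emp.values - ref)) * h / denom
        rows.append((t, err))
    if not rows:
        raise ValueError("trajectory and kymograph share no snapshot times")
    return np.asarray(rows)


def summary_row(kymo: Kymograph, threshold: float = 5.0) -> dict:
    """One-line run summary (config echo + mass drift + aggregate statistics)."""
    agg = detect_aggregates(kymo.final(), threshold)
    mass0 = kymo.mass[0]
    drift = float(np.max(np.abs(kymo.mass - mass0)) / mass0)
    row = dict(kymo.config)
    row.update(
        {
            "mass_initial": mass0,
            "mass_drift_rel": drift,
            "aggregates": agg.count,
            "min_spacing": agg.min_spacing,
            "peak_max": float(kymo.U[-1].max()),
            "threshold": threshold,
        }
    )
    return row
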