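"""Downsampling of high-frequency trajectories and step-wise statistics.

Simulations run at a much higher temporal resolution than field telemetry;
comparisons with observed tracks therefore happen after thinning the
simulated track to every ``m``-th location and recomputing step lengths,
turning angles and accumulated resistance at that coarser scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import wasserstein_distance

from .landscape import ResistanceRaster, resistance_at
from .sim import Trajectory

__all__ = [
    "ResampledTrack",
    "sample_movement",
    "wrap_angle",
    "turning_angles",
    "histogram",
    "angular_histogram",
    "distribution_distance",
]


def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    w = np.mod(np.asarray(a, dtype=np.float64) + np.pi, 2.0 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


def turning_angles(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Signed heading changes between consecutive steps of a track, in (-pi, pi]."""
    headings = np.arctan2(np.diff(y), np.diff(x))
    return wrap_angle(np.diff(headings))


@dataclass
class ResampledTrack:
    """Every m-th location of a track plus per-step statistics.

    ``step_lengths`` has one entry per resampled step (n_kept - 1) and
    ``turning_angles`` one per interior location (n_kept - 2).
    ``accumulated_resistance`` sums the resistance at the m - 1 skipped
    high-frequency locations *within* each resampled step (the kept
    endpoints are not included); it is all zero when no raster is given.
    """

    x: np.ndarray
    y: np.ndarray
    m: int
    step_lengths: np.ndarray
    turning_angles: np.ndarray
    accumulated_resistance: np.ndarray

    def __len__(self) -> int:
        return len(self.x)


def sample_movement(
    traj: Trajectory, m: int, raster: ResistanceRaster | None = None
) -> ResampledTrack:
    """Thin a trajectory to every ``m``-th location and compute step statistics."""
    if m < 1:
        raise ValueError("downsampling factor m must be >= 1")
    n = len(traj)
    if n <= 2 * m:
        raise ValueError(f"trajectory of {n} locations is too short for m={m} (need > {2 * m})")
    keep = np.arange(0, n, m)
    x = traj.x[keep].copy()
    y = traj.y[keep].copy()
    step_lengths = np.hypot(np.diff(x), np.diff(y))
    angles = turning_angles(x, y)

    accum = np.zeros(len(keep) - 1)
    if raster is not None and m > 1:
        for i in range(len(keep) - 1):
            mid = slice(keep[i] + 1, keep[i + 1])
            accum[i] = float(np.sum(resistance_at(raster, traj.x[mid], traj.y[mid])))
    return ResampledTrack(x, y, m, step_lengths, angles, accum)


def histogram(values, bin_edges) -> np.ndarray:
    """Bin counts with left-closed bins; the last bin also closed on the right."""
    edges = np.asarray(bin_edges, dtype=np.float64)
    if edges.ndim != 1 or len(edges) < 3:
        raise ValueError("need at least 2 bins (3 edges)")
    if not (np.diff(edges) > 0).all():
        raise ValueError("bin edges must be strictly increasing")
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        return np.zeros(len(edges) - 1, dtype=np.int64)
    counts, _ = np.histogram(values, bins=edges)
    return counts.astype(np.int64)


def angular_histogram(angles, n_bins: int = 16) -> np.ndarray:
    """Counts of angles over ``n_bins`` equal bins spanning (-pi, pi]."""
    if n_bins < 2:
        raise ValueError("need at least 2 angular bins")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    return histogram(wrap_angle(np.asarray(angles, dtype=np.float64)), edges)


def distribution_distance(counts_a, counts_b, metric: str = "l1", bin_centers=None) -> float:
    """Distance between two binned distributions, compared as relative frequencies.

    ``"l1"`` (default) is the total absolute difference of the two
    relative-frequency vectors: 0 for identical shapes, 2 for disjoint
    single-bin masses.  ``"wasserstein"`` is the 1-Wasserstein distance on
    the bin centers (which must then be supplied) — an alternative metric
    for track comparison.
    """
    a = np.asarray(counts_a, dtype=np.float64)
    b = np.asarray(counts_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("count vectors must share the binning")
    ta, tb = a.sum(), b.sum()
    if ta == 0 and tb == 0:
        return 0.0
    pa = a / ta if ta > 0 else a
    pb = b / tb if tb > 0 else b
    if metric == "l1":
        return float(np.abs(pa - pb).sum())
    if metric == "wasserstein":
        if bin_centers is None:
            raise ValueError("wasserstein distance needs bin_centers")
        centers = np.asarray(bin_centers, dtype=np.float64)
        return float(wasserstein_distance(centers, centers, pa, pb))
    raise ValueError(f"unknown metric {metric!r}")
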