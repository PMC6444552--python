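"""The stepping algorithm: perceive, weight headings, draw, move.

Each simulated step proceeds as follows:

1. draw the next behavioral state from the transition matrix;
2. sample resistance along ``K`` radial lines out to the perceptual range;
3. sum the conductances (1 - resistance) per line into an empirical
   angular distribution;
4. build a discrete wrapped-normal turning kernel centered on the previous
   step heading, with the state's concentration;
5. multiply the two distributions;
6. draw the new heading from the product;
7. attenuate the state's maximum step length by the mean resistance of the
   start and intended end points (mean resistance 0 -> full step, 1 -> no
   movement);
8. move, guarding against landing on an impassable (resistance 1) cell.

All headings live on a discrete grid of ``K`` regularly spaced angles
(default 72, i.e. 5 degree resolution).  With no raster the algorithm
reduces to a classical multistate (correlated) random walk with constant
step lengths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._core import _simulate_loop
from .landscape import ResistanceRaster, resistance_at
from .movement import Species

__all__ = [
    "AngularGrid",
    "AngularDistribution",
    "Trajectory",
    "wrapped_normal_weights",
    "turning_kernel",
    "perception_distribution",
    "combine",
    "draw_heading",
    "step_fraction",
    "advance",
    "default_samples_per_line",
    "simulate",
]

logger = logging.getLogger(__name__)

_SERIES_TOL = 1e-12
_POINT_MASS_RHO = 1.0 - 1e-8


@dataclass(frozen=True)
class AngularGrid:
    """K regularly spaced headings theta_k = 2 pi k / K, counterclockwise from +x."""

    K: int = 72

    def __post_init__(self) -> None:
        if self.K < 8:
            raise ValueError("angular grid needs at least 8 headings")

    @property
    def angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.K) / self.K

    def nearest_index(self, heading: float) -> int:
        """Grid index closest to an arbitrary heading (ties to the lower index)."""
        frac = (heading / (2.0 * np.pi) * self.K) % self.K
        idx = int(np.round(frac)) % self.K
        # round() half-to-even can pick the upper neighbour; prefer lower on exact ties
        lower = int(np.floor(frac)) % self.K
        if abs(frac - np.floor(frac) - 0.5) < 1e-15:
            idx = lower
        return idx


@dataclass
class AngularDistribution:
    """Nonnegative weights over the headings of an :class:`AngularGrid`.

    Weights need not be normalized (the perception weights are raw
    conductance sums); :meth:`normalized` rescales to sum 1.
    """

    grid: AngularGrid
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != (self.grid.K,):
            raise ValueError(f"weights must have shape ({self.grid.K},)")
        if (w < 0).any():
            raise ValueError("angular weights must be nonnegative")
        self.weights = w

    @property
    def total(self) -> float:
        return float(np.cumsum(self.weights)[-1])

    def normalized(self) -> "AngularDistribution":
        t = self.total
        if t <= 0:
            raise ValueError("cannot normalize an all-zero angular distribution")
        return AngularDistribution(self.grid, self.weights / t)

    def mean_resultant_length(self) -> float:
        w = self.normalized().weights
        z = np.sum(w * np.exp(1j * self.grid.angles))
        return float(abs(z))


def wrapped_normal_weights(grid: AngularGrid, concentration: float, center: float = 0.0) -> np.ndarray:
    """Discrete wrapped-normal density on the grid, normalized to sum 1.

    The concentration is the mean resultant length rho in [0, 1]
    (rho = exp(-sigma^2 / 2)); the density is evaluated through the wrapped
    series ``f(t) = (1/2pi) [1 + 2 sum_p rho^(p^2) cos(p (t - mu))]``,
    truncated once ``rho^(p^2) < 1e-12``.  rho = 0 is exactly uniform;
    rho -> 1 degenerates to a point mass at the grid angle nearest ``mu``.
    """
    K = grid.K
    if not 0.0 <= concentration <= 1.0:
        raise ValueError("concentration must be in [0, 1]")
    if concentration == 0.0:
        return np.full(K, 1.0 / K)
    if concentration >= _POINT_MASS_RHO:
        w = np.zeros(K)
        w[grid.nearest_index(center)] = 1.0
        return w
    delta = grid.angles - center
    dens = np.ones(K)
    p = 1
    while True:
        coef = concentration ** (p * p)
        if coef < _SERIES_TOL:
            break
        dens += 2.0 * coef * np.cos(p * delta)
        p += 1
    dens = np.maximum(dens, 0.0)  # truncation can dip slightly negative at the antipode
    return dens / np.cumsum(dens)[-1]


def turning_kernel(previous_heading: float, concentration: float, grid: AngularGrid) -> AngularDistribution:
    """Discrete wrapped-normal turning kernel centered on the previous heading."""
    return AngularDistribution(
        grid, wrapped_normal_weights(grid, concentration, center=previous_heading)
    )


def default_samples_per_line(perceptual_range: float, cell_size: float) -> int:
    """At-least-half-cell-dense radial sampling: max(2, ceil(R / (cell/2)))."""
    return max(2, int(math.ceil(perceptual_range / (cell_size / 2.0))))


def perception_distribution(
    raster: ResistanceRaster | None,
    location: tuple[float, float],
    perceptual_range: float,
    grid: AngularGrid,
    samples_per_line: int,
) -> AngularDistribution:
    """Empirical angular distribution of landscape conductance.

    Weight k is the sum of conductance (1 - resistance) at
    ``samples_per_line`` points regularly spaced along the radial line of
    heading theta_k, out to the perceptual range.  Out-of-extent samples
    contribute conductance 0; with no raster all weights are equal.
    """
    if samples_per_line < 1:
        raise ValueError("samples_per_line must be >= 1")
    K = grid.K
    if raster is None:
        return AngularDistribution(grid, np.full(K, float(samples_per_line)))
    x, y = location
    j = np.arange(1, samples_per_line + 1)
    dist = perceptual_range * j / samples_per_line  # (n,)
    ang = grid.angles
    px = x + np.outer(np.cos(ang), dist)  # (K, n)
    py = y + np.outer(np.sin(ang), dist)
    conduct = 1.0 - resistance_at(raster, px, py)
    weights = np.cumsum(conduct, axis=1)[:, -1]  # sequential per-line sums
    return AngularDistribution(grid, weights)


def combine(empirical: AngularDistribution, kernel: AngularDistribution) -> AngularDistribution:
    """Product of the perception and turning distributions, normalized.

    If every product weight is zero (walker boxed in by impassable cells in
    all kernel-supported directions) the kernel alone is returned, so the
    draw stays defined; the subsequent movement guard then yields a
    zero-length step.
    """
    if empirical.grid.K != kernel.grid.K:
        raise ValueError("distributions must share the angular grid")
    prod = empirical.weights * kernel.weights
    total = float(np.cumsum(prod)[-1])
    if total <= 0.0:
        logger.debug("all-zero combined distribution; falling back to the kernel")
        return kernel.normalized()
    return AngularDistribution(kernel.grid, prod / total)


def draw_heading(dist: AngularDistribution, rng: np.random.Generator) -> float:
    """Draw a grid heading with probability proportional to its weight."""
    w = dist.weights
    cdf = np.cumsum(w)
    total = cdf[-1]
    if total <= 0:
        raise ValueError("cannot draw from an all-zero distribution")
    target = rng.random() * total
    k = int(np.searchsorted(cdf, target, side="right"))
    if k >= dist.grid.K:
        k = dist.grid.K - 1
    return float(dist.grid.angles[k])


def step_fraction(
    raster: ResistanceRaster | None,
    from_xy: tuple[float, float],
    intended_to: tuple[float, float],
) -> float:
    """Fraction of the step actually taken: 1 - mean endpoint resistance."""
    if raster is None:
        return 1.0
    rf = resistance_at(raster, *from_xy)
    rt = resistance_at(raster, *intended_to)
    return 1.0 - (rf + rt) / 2.0


def advance(
    location: tuple[float, float],
    heading: float,
    state,
    raster: ResistanceRaster | None,
) -> tuple[float, float]:
    """One movement update: attenuate by resistance, then apply the guard.

    The intended endpoint is ``location + L (cos h, sin h)`` with ``L`` the
    state's maximum step length; the realized distance is scaled by
    :func:`step_fraction`.  If the landing cell is impassable (resistance
    1), the walker is pulled back along the segment, in increments of a
    quarter cell, to the farthest passable point — or stays in place.
    """
    x, y = location
    L = state.max_step_length
    c, s = math.cos(heading), math.sin(heading)
    if raster is None:
        return (x + L * c, y + L * s)
    frac = step_fraction(raster, (x, y), (x + L * c, y + L * s))
    d = frac * L
    if d > 0.0 and resistance_at(raster, x + d * c, y + d * s) >= 1.0:
        dd = d - raster.cell_size * 0.25
        found = False
        while dd > 0.0:
            if resistance_at(raster, x + dd * c, y + dd * s) < 1.0:
                found = True
                break
            dd -= raster.cell_size * 0.25
        d = dd if found else 0.0
    if d <= 0.0:
        return (x, y)
    return (x + d * c, y + d * s)


@dataclass
class Trajectory:
    """High-frequency simulated track: one row per step plus the start."""

    step: np.ndarray
    x: np.ndarray
    y: np.ndarray
    state: np.ndarray
    seed: int | None = None
    n_trapped: int = 0

    def __len__(self) -> int:
        return len(self.step)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def displacements(self) -> np.ndarray:
        """Euclidean distance between consecutive locations."""
        return np.hypot(np.diff(self.x), np.diff(self.y))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": self.step, "x": self.x, "y": self.y, "state": self.state}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Trajectory":
        return cls(
            step=df["step"].to_numpy(np.int64),
            x=df["x"].to_numpy(np.float64),
            y=df["y"].to_numpy(np.float64),
            state=df["state"].to_numpy(np.int64),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        return cls.from_dataframe(pd.read_csv(path))


def _prepare_arrays(species: Species, raster: ResistanceRaster | None, grid: AngularGrid,
                    samples_per_line: int | None):
    S = species.n_states
    K = grid.K
    kernels = np.empty((S, K))
    for i, st in enumerate(species.states):
        kernels[i] = wrapped_normal_weights(grid, st.concentration, center=0.0)
    max_steps = np.array([st.max_step_length for st in species.states])
    perc = np.array([st.perceptual_range for st in species.states])
    if raster is None:
        n_samp = np.full(S, 2, dtype=np.int64)
    elif samples_per_line is not None:
        n_samp = np.full(S, int(samples_per_line), dtype=np.int64)
    else:
        n_samp = np.array(
            [default_samples_per_line(st.perceptual_range, raster.cell_size)
             for st in species.states],
            dtype=np.int64,
        )
    return kernels, max_steps, perc, n_samp


def simulate(
    species: Species,
    n_steps: int,
    raster: ResistanceRaster | None = None,
    start: tuple[float, float] = (0.0, 0.0),
    start_state: int = 0,
    start_heading: float | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    grid: AngularGrid | None = None,
    samples_per_line: int | None = None,
    engine: str = "numba",
) -> Trajectory:
    """Simulate a multistate walk of ``n_steps`` steps.

    Returns a trajectory of ``n_steps + 1`` rows (including the start).
    Fully reproducible: the same ``seed`` (or generator state) and inputs
    give bit-identical output regardless of engine (``"numba"`` is the fast
    JIT path, ``"python"`` a reference implementation of the same
    arithmetic).

    ``start_heading`` is snapped to the angular grid; by default it is
    drawn uniformly from the grid.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not 0 <= start_state < species.n_states:
        raise ValueError(f"start_state {start_state} invalid for {species.n_states} states")
    if raster is not None and resistance_at(raster, *start) >= 1.0:
        raise ValueError("start location lies on an impassable (resistance 1) cell")
    grid = grid or AngularGrid()
    if rng is None:
        rng = np.random.default_rng(seed)

    K = grid.K
    if start_heading is None:
        heading_idx = min(int(rng.random() * K), K - 1)
    else:
        heading_idx = grid.nearest_index(start_heading)

    kernels, max_steps, perc, n_samp = _prepare_arrays(species, raster, grid, samples_per_line)
    angles = grid.angles
    cos_t = np.cos(angles)
    sin_t = np.sin(angles)

    has_raster = raster is not None
    if has_raster:
        values, rx0, ry0, rcell = raster.values, raster.origin_x, raster.origin_y, raster.cell_size
    else:
        values, rx0, ry0, rcell = np.zeros((1, 1)), 0.0, 0.0, 1.0

    if engine == "numba":
        xs, ys, states, n_trapped, _ = _simulate_loop(
            n_steps, float(start[0]), float(start[1]), start_state, heading_idx,
            species.transitions.probs, kernels, max_steps, perc, n_samp,
            cos_t, sin_t, has_raster, values, rx0, ry0, rcell, rng,
        )
    elif engine == "python":
        xs, ys, states, n_trapped = _simulate_python(
            n_steps, float(start[0]), float(start[1]), start_state, heading_idx,
            species.transitions.probs, kernels, max_steps, perc, n_samp,
            cos_t, sin_t, raster, rng,
        )
    else:
        raise ValueError(f"unknown engine {engine!r}")

    return Trajectory(
        step=np.arange(n_steps + 1, dtype=np.int64),
        x=xs, y=ys, state=states, seed=seed, n_trapped=n_trapped,
    )


def _simulate_python(
    n_steps, x, y, state, heading_idx, trans, kernels, max_steps, perc_ranges,
    n_samples, cos_t, sin_t, raster, rng,
):
    """Reference engine; mirrors ``_core._simulate_loop`` exactly."""
    K = cos_t.shape[0]
    S = trans.shape[0]
    if raster is not None:
        values, rx0, ry0, rcell = raster.values, raster.origin_x, raster.origin_y, raster.cell_size
        nrow, ncol = values.shape

        def res(px, py):
            col = int(np.floor((px - rx0) / rcell))
            row_b = int(np.floor((py - ry0) / rcell))
            if col < 0 or col >= ncol or row_b < 0 or row_b >= nrow:
                return 1.0
            return values[nrow - 1 - row_b, col]

    xs = np.empty(n_steps + 1)
    ys = np.empty(n_steps + 1)
    states = np.empty(n_steps + 1, dtype=np.int64)
    xs[0], ys[0], states[0] = x, y, state
    n_trapped = 0
    for t in range(1, n_steps + 1):
        u1 = rng.random()
        acc = 0.0
        s = S - 1
        for j in range(S - 1):
            acc += trans[state, j]
            if u1 < acc:
                s = j
                break
        state = s

        if raster is not None:
            R = perc_ranges[s]
            n = n_samples[s]
            perc = np.empty(K)
            for k in range(K):
                w = 0.0
                for j in range(1, n + 1):
                    d = R * j / n
                    w += 1.0 - res(x + d * cos_t[k], y + d * sin_t[k])
                perc[k] = w
        else:
            perc = np.ones(K)

        combined = np.empty(K)
        total = 0.0
        for k in range(K):
            combined[k] = perc[k] * kernels[s, (k - heading_idx) % K]
            total += combined[k]
        if total <= 0.0:
            n_trapped += 1
            total = 0.0
            for k in range(K):
                combined[k] = kernels[s, (k - heading_idx) % K]
                total += combined[k]

        u2 = rng.random()
        target = u2 * total
        acc = 0.0
        h = K - 1
        for k in range(K):
            acc += combined[k]
            if target < acc:
                h = k
                break

        L = max_steps[s]
        dx = L * cos_t[h]
        dy = L * sin_t[h]
        if raster is not None:
            rf = res(x, y)
            rt = res(x + dx, y + dy)
            frac = 1.0 - (rf + rt) / 2.0
        else:
            frac = 1.0
        d = frac * L

        if raster is not None and d > 0.0:
            if res(x + d * cos_t[h], y + d * sin_t[h]) >= 1.0:
                dd = d - rcell * 0.25
                found = False
                while dd > 0.0:
                    if res(x + dd * cos_t[h], y + dd * sin_t[h]) < 1.0:
                        found = True
                        break
                    dd -= rcell * 0.25
                d = dd if found else 0.0

        if d > 0.0:
            x = x + d * cos_t[h]
            y = y + d * sin_t[h]
            heading_idx = h

        xs[t], ys[t], states[t] = x, y, state
    return xs, ys, states, n_trapped
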