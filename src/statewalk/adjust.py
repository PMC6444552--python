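"""Pattern-oriented approximation of simulation parameters from observed tracks.

Observed telemetry is typically sampled far less often than the simulation
runs, so likelihood-based estimation of the high-frequency parameters is
impractical.  Instead, parameters are *approximated* pattern-oriented-
modelling style: candidate parameter vectors are simulated at high
frequency, downsampled to the observation frequency, and scored by how
closely their turning-angle and step-length distributions match the
observed ones.  The two distribution distances are minimized jointly with
the elitist multi-objective genetic algorithm NSGA-II (fast nondominated
sorting, crowding distance, binary tournament, simulated binary crossover,
polynomial mutation, (mu + lambda) survivor selection), yielding a Pareto
front of plausible parameter sets rather than a single point estimate.

The modelling interface is ``MovementCalibration(observed, template, m)``
whose :meth:`~MovementCalibration.fit` returns a
:class:`CalibrationResults` with the front, the per-generation trace and a
``summary()`` table; :func:`adjust_model` is the equivalent one-call
functional form.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import ResistanceRaster
from .movement import MovementState, Species, make_transition_matrix
from .resample import (
    ResampledTrack,
    angular_histogram,
    distribution_distance,
    histogram,
    sample_movement,
    turning_angles,
)
from .sim import AngularGrid, Trajectory, simulate

__all__ = [
    "SpeciesModelTemplate",
    "decode",
    "encode",
    "evaluate",
    "nsga2",
    "GenerationTrace",
    "MovementCalibration",
    "CalibrationResults",
    "adjust_model",
    "hypervolume_2d",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameter vector <-> species
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesModelTemplate:
    """Search-space definition for parameter approximation.

    The real-valued parameter vector is laid out as, per state, the pair
    ``(concentration, max_step_length)``, followed (for multistate models)
    by the off-diagonal transition probabilities in row-major order.
    Perceptual ranges are fixed, not searched: they only influence the
    generated movements when varied over orders of magnitude, which makes
    them weakly identifiable from track statistics alone.

    A parameter can be pinned by giving it equal lower and upper bounds.
    """

    n_states: int
    perceptual_ranges: tuple[float, ...]
    concentration_bounds: tuple[tuple[float, float], ...]
    step_length_bounds: tuple[tuple[float, float], ...]
    transition_bounds: tuple[tuple[float, float], ...] = ()
    state_labels: tuple[str, ...] = ()
    name: str = "model"

    def __post_init__(self) -> None:
        S = self.n_states
        if S < 1:
            raise ValueError("n_states must be >= 1")
        if len(self.perceptual_ranges) != S:
            raise ValueError("need one perceptual range per state")
        if len(self.concentration_bounds) != S or len(self.step_length_bounds) != S:
            raise ValueError("need one (lo, hi) bound pair per state")
        n_trans = S * (S - 1)
        if len(self.transition_bounds) != n_trans:
            raise ValueError(f"need {n_trans} transition bound pairs, got {len(self.transition_bounds)}")
        for lo, hi in (*self.concentration_bounds, *self.transition_bounds):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("concentration/transition bounds must satisfy 0 <= lo <= hi <= 1")
        for lo, hi in self.step_length_bounds:
            if not (0.0 <= lo <= hi):
                raise ValueError("step-length bounds must satisfy 0 <= lo <= hi")
        if not self.state_labels:
            object.__setattr__(self, "state_labels", tuple(f"state{i}" for i in range(S)))

    @classmethod
    def default(
        cls,
        n_states: int,
        perceptual_range: float = 100.0,
        max_step_length: float = 50.0,
        max_switching_prob: float | None = None,
        name: str = "model",
    ) -> "SpeciesModelTemplate":
        """Template with the customary search box: rho in [0, 1], step length
        in [0, max], switching probabilities bounded so row sums stay <= 1."""
        S = n_states
        if max_switching_prob is None:
            max_switching_prob = min(1.0, 1.0 / max(1, S - 1))
        return cls(
            n_states=S,
            perceptual_ranges=(perceptual_range,) * S,
            concentration_bounds=((0.0, 1.0),) * S,
            step_length_bounds=((0.0, max_step_length),) * S,
            transition_bounds=((0.0, max_switching_prob),) * (S * (S - 1)),
            name=name,
        )

    @property
    def n_params(self) -> int:
        return 2 * self.n_states + self.n_states * (self.n_states - 1)

    @property
    def param_names(self) -> tuple[str, ...]:
        names = []
        for i in range(self.n_states):
            names += [f"concentration_{i}", f"step_length_{i}"]
        for i in range(self.n_states):
            for j in range(self.n_states):
                if i != j:
                    names.append(f"p_switch_{i}{j}")
        return tuple(names)

    @property
    def lower(self) -> np.ndarray:
        return np.array(
            [b[0] for pair in zip(self.concentration_bounds, self.step_length_bounds) for b in pair]
            + [b[0] for b in self.transition_bounds]
        )

    @property
    def upper(self) -> np.ndarray:
        return np.array(
            [b[1] for pair in zip(self.concentration_bounds, self.step_length_bounds) for b in pair]
            + [b[1] for b in self.transition_bounds]
        )


def decode(template: SpeciesModelTemplate, vector) -> Species:
    """Turn a bounded parameter vector into a simulable :class:`Species`."""
    v = np.asarray(vector, dtype=np.float64)
    if v.shape != (template.n_params,):
        raise ValueError(f"expected vector of length {template.n_params}, got {v.shape}")
    if (v < template.lower - 1e-12).any() or (v > template.upper + 1e-12).any():
        raise ValueError("parameter vector violates template bounds")
    S = template.n_states
    states = tuple(
        MovementState(
            concentration=float(v[2 * i]),
            max_step_length=float(v[2 * i + 1]),
            perceptual_range=template.perceptual_ranges[i],
            label=template.state_labels[i],
        )
        for i in range(S)
    )
    off = np.zeros((S, S))
    idx = 2 * S
    for i in range(S):
        for j in range(S):
            if i != j:
                off[i, j] = v[idx]
                idx += 1
    if S > 1:
        row_sums = off.sum(axis=1)
        if (row_sums > 1.0).any():  # renormalize rows the bounds could not prevent
            over = row_sums > 1.0
            off[over] /= row_sums[over, None]
    return Species(states, make_transition_matrix(off), name=template.name)


def encode(species: Species, template: SpeciesModelTemplate) -> np.ndarray:
    """Inverse of :func:`decode` for species matching the template layout."""
    if species.n_states != template.n_states:
        raise ValueError("species/template state-count mismatch")
    S = species.n_states
    v = np.empty(template.n_params)
    for i, st in enumerate(species.states):
        v[2 * i] = st.concentration
        v[2 * i + 1] = st.max_step_length
    idx = 2 * S
    for i in range(S):
        for j in range(S):
            if i != j:
                v[idx] = species.transitions.probs[i, j]
                idx += 1
    return v


# ---------------------------------------------------------------------------
# objective evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _ObservedSummary:
    """Precomputed histograms of the observed track, shared by all candidates."""

    angle_counts: np.ndarray
    length_counts: np.ndarray
    length_edges: np.ndarray
    n_angle_bins: int
    n_obs_steps: int


def _summarize_observed(
    step_lengths: np.ndarray,
    angles: np.ndarray,
    n_angle_bins: int,
    n_length_bins: int,
) -> _ObservedSummary:
    max_len = float(np.max(step_lengths)) if len(step_lengths) else 1.0
    if max_len <= 0:
        max_len = 1.0
    edges = np.linspace(0.0, max_len * 1.1, n_length_bins + 1)
    return _ObservedSummary(
        angle_counts=angular_histogram(angles, n_angle_bins),
        length_counts=histogram(step_lengths, edges),
        length_edges=edges,
        n_angle_bins=n_angle_bins,
        n_obs_steps=len(step_lengths),
    )


def evaluate(
    candidate_vector,
    template: SpeciesModelTemplate,
    observed: _ObservedSummary | ResampledTrack,
    m: int,
    n_sim_steps: int,
    raster: ResistanceRaster | None = None,
    rng: np.random.Generator | None = None,
    start: tuple[float, float] = (0.0, 0.0),
    grid: AngularGrid | None = None,
    metric: str = "l1",
    n_angle_bins: int = 16,
    n_length_bins: int = 20,
) -> np.ndarray:
    """Objective vector (turning-angle distance, step-length distance).

    The candidate is decoded, simulated for ``n_sim_steps`` high-frequency
    steps, downsampled by ``m``, and its histograms are compared against
    the observed ones on the observed track's binning.  Simulated step
    lengths beyond the observed range are clipped into the outer bin so
    that grossly wrong candidates score the full disjoint-histogram
    distance instead of losing mass.
    """
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(observed, ResampledTrack):
        observed = _summarize_observed(
            observed.step_lengths, observed.turning_angles, n_angle_bins, n_length_bins
        )
    if n_sim_steps < m * observed.n_obs_steps:
        raise ValueError("n_sim_steps must cover m x (observed steps)")
    species = decode(template, candidate_vector)
    traj = simulate(
        species, n_sim_steps, raster=raster, start=start, rng=rng, grid=grid
    )
    track = sample_movement(traj, m)
    lengths = np.clip(track.step_lengths, observed.length_edges[0], observed.length_edges[-1])
    angle_counts = angular_histogram(track.turning_angles, observed.n_angle_bins)
    length_counts = histogram(lengths, observed.length_edges)
    centers_a = None
    centers_l = None
    if metric == "wasserstein":
        edges_a = np.linspace(-np.pi, np.pi, observed.n_angle_bins + 1)
        centers_a = (edges_a[:-1] + edges_a[1:]) / 2
        centers_l = (observed.length_edges[:-1] + observed.length_edges[1:]) / 2
    return np.array(
        [
            distribution_distance(angle_counts, observed.angle_counts, metric, centers_a),
            distribution_distance(length_counts, observed.length_counts, metric, centers_l),
        ]
    )


# ---------------------------------------------------------------------------
# NSGA-II
# ---------------------------------------------------------------------------

def _fast_non_dominated_sort(F: np.ndarray) -> np.ndarray:
    """Nondomination rank (0 = Pareto front) of each row of objectives F."""
    N = F.shape[0]
    # strict Pareto dominance: <= in all objectives, < in at least one
    le = (F[:, None, :] <= F[None, :, :]).all(axis=2)
    lt = (F[:, None, :] < F[None, :, :]).any(axis=2)
    dominates = le & lt  # dominates[i, j]: i dominates j
    n_dominators = dominates.sum(axis=0)
    ranks = np.full(N, -1, dtype=np.int64)
    current = np.where(n_dominators == 0)[0]
    r = 0
    while current.size:
        ranks[current] = r
        n_dominators = n_dominators - dominates[current].sum(axis=0)
        n_dominators[ranks >= 0] = -1
        current = np.where(n_dominators == 0)[0]
        r += 1
    return ranks


def _crowding_distance(F: np.ndarray) -> np.ndarray:
    """Crowding distance within one front; boundary points get +inf."""
    N, M = F.shape
    dist = np.zeros(N)
    for m in range(M):
        order = np.argsort(F[:, m], kind="stable")
        fmin, fmax = F[order[0], m], F[order[-1], m]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if fmax > fmin:
            gaps = (F[order[2:], m] - F[order[:-2], m]) / (fmax - fmin)
            dist[order[1:-1]] += gaps
    return dist


def _rank_and_crowd(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ranks = _fast_non_dominated_sort(F)
    crowd = np.empty(len(F))
    for r in range(ranks.max() + 1):
        idx = np.where(ranks == r)[0]
        crowd[idx] = _crowding_distance(F[idx])
    return ranks, crowd


def _tournament(ranks, crowd, rng) -> int:
    i, j = rng.integers(0, len(ranks), size=2)
    if ranks[i] < ranks[j]:
        return i
    if ranks[j] < ranks[i]:
        return j
    if crowd[i] > crowd[j]:
        return i
    if crowd[j] > crowd[i]:
        return j
    return i if rng.random() < 0.5 else j


def _sbx_crossover(p1, p2, lower, upper, eta, p_cross, rng):
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() > p_cross:
        return c1, c2
    for k in range(len(p1)):
        if rng.random() > 0.5 or upper[k] <= lower[k]:
            continue
        u = rng.random()
        if u <= 0.5:
            beta = (2.0 * u) ** (1.0 / (eta + 1.0))
        else:
            beta = (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0))
        v1 = 0.5 * ((1 + beta) * p1[k] + (1 - beta) * p2[k])
        v2 = 0.5 * ((1 - beta) * p1[k] + (1 + beta) * p2[k])
        c1[k] = min(max(v1, lower[k]), upper[k])
        c2[k] = min(max(v2, lower[k]), upper[k])
    return c1, c2


def _polynomial_mutation(x, lower, upper, eta, p_mut, rng):
    y = x.copy()
    for k in range(len(x)):
        if rng.random() > p_mut or upper[k] <= lower[k]:
            continue
        u = rng.random()
        if u < 0.5:
            delta = (2.0 * u) ** (1.0 / (eta + 1.0)) - 1.0
        else:
            delta = 1.0 - (2.0 * (1.0 - u)) ** (1.0 / (eta + 1.0))
        y[k] = min(max(x[k] + delta * (upper[k] - lower[k]), lower[k]), upper[k])
    return y


@dataclass
class GenerationTrace:
    """Per-generation record of an NSGA-II run.

    ``fronts[g]`` is the ``(params, objectives)`` pair of the nondominated
    set after generation ``g`` (generation 0 is the initial population);
    ``population_min[g]`` holds the generation's minimum of each objective
    over the whole population, which elitism makes non-increasing.
    """

    fronts: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    population_min: list[np.ndarray] = field(default_factory=list)
    param_names: tuple[str, ...] = ()
    objective_names: tuple[str, ...] = ("angle_distance", "length_distance")

    @property
    def n_generations(self) -> int:
        return len(self.fronts) - 1

    @property
    def final_front(self) -> tuple[np.ndarray, np.ndarray]:
        return self.fronts[-1]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for g, (P, F) in enumerate(self.fronts):
            for p, f in zip(P, F):
                row = {"generation": g}
                names = self.param_names or tuple(f"x{k}" for k in range(P.shape[1]))
                row.update(dict(zip(names, p)))
                row.update(dict(zip(self.objective_names, f)))
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def nsga2(
    evaluate_fn,
    lower,
    upper,
    pop_size: int,
    n_generations: int,
    rng: np.random.Generator,
    eta_crossover: float = 15.0,
    eta_mutation: float = 20.0,
    crossover_prob: float = 0.9,
    mutation_prob: float | None = None,
    param_names: tuple[str, ...] = (),
) -> GenerationTrace:
    """Elitist NSGA-II minimization over a box-bounded real search space.

    ``evaluate_fn(x, rng) -> objective vector`` may be stochastic; survivor
    objectives are *not* re-evaluated, so with (mu + lambda) selection the
    population minimum of each recorded objective is non-increasing.
    """
    lower = np.asarray(lower, dtype=np.float64)
    upper = np.asarray(upper, dtype=np.float64)
    n_var = len(lower)
    if pop_size < 4 or pop_size % 2:
        raise ValueError("pop_size must be even and >= 4")
    if mutation_prob is None:
        mutation_prob = 1.0 / n_var

    pop = lower + rng.random((pop_size, n_var)) * (upper - lower)
    F = np.array([evaluate_fn(x, rng) for x in pop])
    if not (np.isfinite(F).all() and (F >= 0).all()):
        raise ValueError("objectives must be finite and nonnegative")
    ranks, crowd = _rank_and_crowd(F)

    trace = GenerationTrace(param_names=tuple(param_names))
    _record(trace, pop, F, ranks)

    for _ in range(n_generations):
        offspring = []
        while len(offspring) < pop_size:
            a = _tournament(ranks, crowd, rng)
            b = _tournament(ranks, crowd, rng)
            c1, c2 = _sbx_crossover(pop[a], pop[b], lower, upper, eta_crossover, crossover_prob, rng)
            offspring.append(_polynomial_mutation(c1, lower, upper, eta_mutation, mutation_prob, rng))
            if len(offspring) < pop_size:
                offspring.append(
                    _polynomial_mutation(c2, lower, upper, eta_mutation, mutation_prob, rng)
                )
        off = np.array(offspring)
        F_off = np.array([evaluate_fn(x, rng) for x in off])

        both = np.vstack([pop, off])
        F_both = np.vstack([F, F_off])
        ranks_b, crowd_b = _rank_and_crowd(F_both)
        # survivor selection: by rank, then descending crowding
        order = np.lexsort((-crowd_b, ranks_b))[:pop_size]
        pop, F = both[order], F_both[order]
        ranks, crowd = _rank_and_crowd(F)
        _record(trace, pop, F, ranks)

    return trace


def _record(trace: GenerationTrace, pop, F, ranks) -> None:
    front = np.where(ranks == 0)[0]
    trace.fronts.append((pop[front].copy(), F[front].copy()))
    trace.population_min.append(F.min(axis=0))


def hypervolume_2d(objectives: np.ndarray, reference: tuple[float, float]) -> float:
    """Hypervolume dominated by a 2-objective front w.r.t. a reference point."""
    F = np.asarray(objectives, dtype=np.float64)
    ranks = _fast_non_dominated_sort(F)
    F = F[ranks == 0]
    F = F[np.lexsort((F[:, 1], F[:, 0]))]
    rx, ry = reference
    hv = 0.0
    prev_y = ry
    for f1, f2 in F:
        if f1 >= rx or f2 >= prev_y:
            continue
        hv += (rx - f1) * (prev_y - f2)
        prev_y = f2
    return hv


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------

def _regularize_track(df: pd.DataFrame) -> list[np.ndarray]:
    """Split a (possibly time-stamped) track into near-regular segments.

    Without timestamps the whole track is a single segment.  With a
    ``time`` column, fixes are thinned to the modal sampling interval and
    the track is split wherever a gap exceeds 1.5x that interval; segment
    statistics are pooled downstream.
    """
    coords = df[["x", "y"]].to_numpy(np.float64)
    if "time" not in df.columns:
        return [coords]
    t = df["time"].to_numpy(np.float64)
    order = np.argsort(t, kind="stable")
    t, coords = t[order], coords[order]
    dt = np.diff(t)
    dt = dt[dt > 0]
    if dt.size == 0:
        return [coords]
    vals, counts = np.unique(np.round(dt, 6), return_counts=True)
    modal = float(vals[np.argmax(counts)])
    # thin to the modal interval
    kept = [0]
    for i in range(1, len(t)):
        if t[i] - t[kept[-1]] >= modal * 0.999:
            kept.append(i)
    t, coords = t[kept], coords[kept]
    gaps = np.where(np.diff(t) > 1.5 * modal)[0]
    segments = []
    start = 0
    for g in gaps:
        segments.append(coords[start : g + 1])
        start = g + 1
    segments.append(coords[start:])
    return [s for s in segments if len(s) >= 2]


class MovementCalibration:
    """Approximate simulation parameters from an observed low-frequency track.

    Parameters
    ----------
    observed
        The track: a DataFrame with columns ``x, y[, time]``, an (n, 2)
        coordinate array, or a precomputed :class:`ResampledTrack`.
    template
        Search-space definition (:class:`SpeciesModelTemplate`).
    m
        Assumed ratio of simulation frequency to observation frequency:
        candidates are simulated at high frequency and thinned by ``m``
        before comparison.
    n_sim_steps
        High-frequency steps per candidate simulation; defaults to
        ``m`` times the number of observed steps.
    raster
        Optional landscape the candidates are simulated on.
    """

    def __init__(
        self,
        observed,
        template: SpeciesModelTemplate,
        m: int,
        n_sim_steps: int | None = None,
        raster: ResistanceRaster | None = None,
        start: tuple[float, float] = (0.0, 0.0),
        n_angle_bins: int = 16,
        n_length_bins: int = 20,
        metric: str = "l1",
    ) -> None:
        if m < 1:
            raise ValueError("m must be >= 1")
        self.template = template
        self.m = m
        self.raster = raster
        self.start = start
        self.metric = metric

        if isinstance(observed, ResampledTrack):
            lengths, angles = observed.step_lengths, observed.turning_angles
            n_locs = len(observed)
        else:
            if isinstance(observed, pd.DataFrame):
                df = observed
            else:
                arr = np.asarray(observed, dtype=np.float64)
                df = pd.DataFrame({"x": arr[:, 0], "y": arr[:, 1]})
            segments = _regularize_track(df)
            n_locs = sum(len(s) for s in segments)
            all_coords = np.vstack(segments)
            if np.allclose(all_coords, all_coords[0]):
                raise ValueError("degenerate observed track: all locations identical")
            lengths = np.concatenate(
                [np.hypot(*np.diff(s, axis=0).T) for s in segments]
            )
            angles = np.concatenate(
                [turning_angles(s[:, 0], s[:, 1]) for s in segments if len(s) >= 3]
            )
        if n_locs < 30:
            warnings.warn(
                f"observed track has only {n_locs} locations; "
                "histograms may be too unstable to calibrate against",
                stacklevel=2,
            )
        self.observed = _summarize_observed(lengths, angles, n_angle_bins, n_length_bins)
        self.n_sim_steps = n_sim_steps or m * max(self.observed.n_obs_steps, 1)
        if self.n_sim_steps < m * self.observed.n_obs_steps:
            raise ValueError("n_sim_steps must cover m x (observed steps)")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, template, m, **kwargs) -> "MovementCalibration":
        return cls(df, template, m, **kwargs)

    def _objective(self, x, rng) -> np.ndarray:
        return evaluate(
            x,
            self.template,
            self.observed,
            self.m,
            self.n_sim_steps,
            raster=self.raster,
            rng=rng,
            start=self.start,
            metric=self.metric,
        )

    def fit(
        self,
        pop_size: int = 100,
        n_generations: int = 50,
        seed: int | None = None,
        eta_crossover: float = 15.0,
        eta_mutation: float = 20.0,
        mutation_prob: float | None = None,
    ) -> "CalibrationResults":
        """Run NSGA-II and return the calibration results."""
        rng = np.random.default_rng(seed)
        trace = nsga2(
            self._objective,
            self.template.lower,
            self.template.upper,
            pop_size,
            n_generations,
            rng,
            eta_crossover=eta_crossover,
            eta_mutation=eta_mutation,
            mutation_prob=mutation_prob,
            param_names=self.template.param_names,
        )
        return CalibrationResults(self, trace, seed=seed)


class CalibrationResults:
    """Pareto front, per-generation trace and diagnostics of a calibration."""

    def __init__(self, model: MovementCalibration, trace: GenerationTrace, seed=None):
        self.model = model
        self.trace = trace
        self.seed = seed
        self.front_params, self.front_objectives = trace.final_front

    @property
    def best_index(self) -> int:
        """Front member minimizing the sum of the two distances (a balanced pick)."""
        return int(np.argmin(self.front_objectives.sum(axis=1)))

    @property
    def best_params(self) -> np.ndarray:
        return self.front_params[self.best_index]

    def best_species(self) -> Species:
        return decode(self.model.template, self.best_params)

    def front_species(self) -> list[Species]:
        return [decode(self.model.template, p) for p in self.front_params]

    def to_csv(self, path) -> None:
        """Export the per-generation front (the generation-plot data)."""
        self.trace.to_csv(path)

    def summary(self) -> str:
        names = self.trace.param_names
        lines = [
            "Movement parameter approximation (NSGA-II, pattern-oriented)",
            "=" * 62,
            f"observed steps: {self.model.observed.n_obs_steps}   "
            f"downsampling m: {self.model.m}   sim steps: {self.model.n_sim_steps}",
            f"generations: {self.trace.n_generations}   "
            f"final front size: {len(self.front_params)}   seed: {self.seed}",
            "",
            "Pareto front (objectives are L1 distances, 0 = identical, 2 = disjoint):",
            f"{'angle_dist':>11} {'length_dist':>12}  " + " ".join(f"{n:>16}" for n in names),
        ]
        order = np.argsort(self.front_objectives[:, 0])
        for i in order:
            f = self.front_objectives[i]
            p = self.front_params[i]
            mark = " *" if i == self.best_index else "  "
            lines.append(
                f"{f[0]:>11.4f} {f[1]:>12.4f}  "
                + " ".join(f"{v:>16.4f}" for v in p)
                + mark
            )
        lines.append("")
        lines.append("* = minimum summed distance")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<CalibrationResults: {len(self.front_params)} front members, "
            f"{self.trace.n_generations} generations>"
        )


def adjust_model(
    observed_track,
    template: SpeciesModelTemplate,
    m: int,
    pop_size: int = 100,
    n_generations: int = 50,
    raster: ResistanceRaster | None = None,
    seed: int | None = None,
    **kwargs,
) -> CalibrationResults:
    """One-call functional form of :class:`MovementCalibration` + ``fit``."""
    model = MovementCalibration(observed_track, template, m, raster=raster, **kwargs)
    return model.fit(pop_size=pop_size, n_generations=n_generations, seed=seed)
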