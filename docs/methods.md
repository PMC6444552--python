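# Methods

## Movement model

A walker carries a behavioral state drawn each step from a row-stochastic
transition matrix (a first-order Markov chain; switching probabilities are
fixed, not habitat- or time-dependent). A state is `(ρ, L, R)`:

* **ρ** — turning-angle concentration, the *mean resultant length* of a
  wrapped-normal kernel (`ρ = exp(−σ²/2)`). This is the only standard
  circular-concentration parameterization bounded in `[0, 1]`: `ρ = 0` is a
  plain random walk, `ρ → 1` a straight line. The kernel density is
  evaluated by the wrapped series
  `f(θ) = (1/2π)[1 + 2 Σ_p ρ^(p²) cos p(θ−μ)]`, truncated once
  `ρ^(p²) < 1e−12` and clipped at 0 (the truncated series can dip
  marginally negative at the antipode for large ρ); `ρ ≥ 1 − 1e−8` is
  treated as a point mass at the grid angle nearest μ.
* **L** — the *maximum* step length, in map units, a fixed number per state
  rather than a distribution. The realized length is attenuated by
  resistance; in free space every step has length exactly L. A state with
  `L = 0` is a Resting state. Keeping L fixed makes it easy to honour the
  rule of thumb that steps should be at most half the width of the
  thinnest landscape feature, so the walker cannot skip across barriers;
  the induced truncation of the realized step-length distribution washes
  out once tracks are downsampled to telemetry resolution.
* **R** — perceptual range, the radius of landscape perception, per state
  (different states may scan at different ranges).

## Landscape and the stepping rule

Resistance rasters hold values in `[0, 1]` on square pixels; cells are
half-open `[x0, x0+c) × [y0, y0+c)` with row 0 at the top in file order,
which makes point lookups unambiguous on edges. Points outside the extent
and NoData cells read as resistance 1 (unknown terrain is impassable — the
conservative choice for a constrained walker), so a trajectory can never
leave the raster. Rasterization of vector features uses a cell-center test
with *last shape wins* overlap semantics; polylines become corridors of
total width `2 × buffer_width`.

Per step, conductance `1 − r` is summed along `K` radial lines (default
`K = 72`, 5° resolution) at `max(2, ceil(R / (c/2)))` regularly spaced
samples per line — at least half-cell dense, so thin features are not
missed between samples. The per-line sums form an empirical angular
distribution that is multiplied by the turning kernel centered on the
previous heading; the new heading is drawn from the (normalized) product on
the discrete grid — headings are never interpolated off-grid. Both
distribution factors may be unnormalized; only the product is normalized,
which changes nothing (normalization constants cancel).

The realized step is `L · (1 − (r_start + r_end)/2)`: zero mean resistance
gives the full step, mean resistance 1 no movement, linearly in between.
Because this averaging alone could still land the walker on an impassable
cell (e.g. a thin barrier between two free cells), an **impassability
guard** then ray-marches back along the segment in quarter-cell increments
to the farthest point with resistance < 1, or leaves the walker in place if
none exists. If the product distribution is identically zero (walker boxed
in within its perceptual range in all kernel-supported directions), the
draw falls back to the kernel alone and the guard yields a zero-length
step: the walker waits rather than teleports; such events are counted on
the trajectory (`n_trapped`).

Two deliberate conventions where the model is silent: the *previous
heading* is the direction of the last step with nonzero displacement, so
zero-length steps (resting, blocked) never randomize orientation — a CRW
resumed after resting continues its old direction; and state switching is
evaluated before the heading draw, so the new state's kernel and
perceptual range govern the current step.

## Determinism and the two engines

One seeded `numpy.random.Generator` is threaded through every draw (one
uniform for the state, one for the heading, per step; one more for a
default start heading). The hot loop is JIT-compiled with numba; a pure
Python reference engine implements the identical arithmetic on the same
RNG stream, and the test suite asserts the two produce bit-identical
trajectories, with and without a raster. Identical seeds and inputs
reproduce trajectories and CLI output files exactly.

## Resampling and track statistics

Downsampling is index-based exact thinning (every *m*-th row; the
simulation step is the clock — timestamped field tracks are first
regularized by the calibration front-end, which thins to the modal sampling
interval and splits at gaps exceeding 1.5× it, pooling segment
statistics). Per resampled step: Euclidean step length, turning angle
wrapped to `(−π, π]`, and accumulated resistance — the sum of resistance at
the `m − 1` skipped interior high-frequency points (endpoints excluded; 0
without a raster). Histograms use left-closed bins with the last bin
closed; defaults are 16 angular bins over `(−π, π]` and 20 length bins over
`[0, 1.1 × max observed length]`. The distribution distance is the L1
difference of relative-frequency vectors (0 identical, 2 disjoint); a
1-Wasserstein option on bin centers is provided as an alternative.

## Parameter approximation

The search space is per-state `(ρ, L)` plus the off-diagonal switching
probabilities, box-bounded; transition bounds default to `1/(S−1)` per
entry so rows always close to a valid stochastic matrix. Perceptual ranges
are fixed by the user, not searched: they alter the movements only when
varied over orders of magnitude, making them weakly identifiable from
track statistics. Each candidate is decoded to a species, simulated at
high frequency (default `m ×` the number of observed steps), thinned by
*m*, and scored by the two L1 distances on the *observed* track's binning;
simulated step lengths beyond the observed range are clipped into the
outer bin so mass is never silently dropped and grossly wrong step lengths
score the full disjoint distance.

NSGA-II uses fast nondominated sorting, crowding distance with infinite
boundary crowding, binary tournament on (rank, crowding) with a random tie
coin, simulated binary crossover (η = 15, probability 0.9, per-variable
0.5), polynomial mutation (η = 20, probability `1/n_params`) and
`(μ+λ)` elitist survivor selection; defaults are population 100 for 50
generations. Objective noise is handled the usual pattern-oriented way:
every candidate gets a fresh simulation seed from the master generator and
is evaluated once (configurable); survivors keep their recorded objective
values, so the per-generation population minimum of each objective is
exactly non-increasing — a property the tests check on every trace.

## Synthetic data

The fixtures module generates all test inputs programmatically:
homogeneous (all-zero) rasters; binary meandering river corridors (a
seeded, laterally correlated centerline buffered to a fixed width — zero
resistance amid resistance 1); dendritic networks (a binary channel tree
with `depth` levels, hence `2^(depth−1)` leaf branches); zero-resistance
patches in a graded matrix; and smooth graded random fields. Corridor
kinds refuse widths under 2 cells, which would violate the step-length
rule of thumb. Default extents are 300×300 cells of size 10 — ample for
10,000-step runs at step length 10 without boundary pinning — and channel
width 6 cells (60 map units ≥ 2 × step length 10). Reference trajectories
bundle the exact generating parameters for recovery scoring.

What the synthetic data does *not* emulate: real telemetry error,
irregular fix schedules beyond simple gaps, habitat preference that is not
expressible as a static resistance surface, and inter-individual
interactions. Passing recovery tests therefore demonstrate that the
calibration can invert the simulator's own generative process at telemetry
resolution — not that it resolves all parameters of free-living animals.

## Problem sizes and numerical choices

Validation uses 50,000-step runs for homogeneous-space kinematics
(concentration recovered within ±0.02), 10⁶ steps for the Markov
machinery, 10,000 steps for confinement, and ten replicates of the
recovery experiment (truth ρ = 0.95, L = 10; 10,000 steps downsampled by
m = 10; population 100, 30 generations) — sizes at which the statistical
checks are decisive while a full run stays desk-scale. Tolerances:
transition-matrix rows must sum to 1 within 1e−12; distribution
normalization is checked to 1e−12; the wrapped series truncates at 1e−12.

## Known limitations

* The binned L1 objective is gradient-free when an observed distribution
  is (nearly) a point mass — e.g. calibrating at `m = 1` against a
  constant-step free-space track; the Wasserstein option is the right
  metric there.
* The two summary distributions (turning angles, step lengths) discard
  serial structure; distinct multistate parameterizations can be
  observationally near-equivalent after downsampling, which is why the
  result is a Pareto front, not a point estimate.
* Resistance is static: no temporal landscapes, no habitat-dependent
  switching, no interactions between individuals.
* Rasters and shapes must share a coordinate system; the CRS string is
  stored pass-through only, with no reprojection.
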