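# statewalk

Mechanistic, spatially-explicit simulation of **multistate animal movements
in resistance landscapes** — including movements constrained to linear
features such as rivers and dendritic networks — plus pattern-oriented
approximation of the simulation parameters from observed low-frequency
(telemetry-like) trajectories.

## Who this is for

Movement ecologists who need biologically plausible *null models* of
individual movement in landscapes that are not homogeneous: river networks,
habitat mosaics, fragmented terrain. Classical correlated-random-walk
simulators assume featureless space; `statewalk` lets the landscape bias
every step, so simulated tracks are comparable with real tracks of
organisms living in linear or heterogeneous habitats.

## The model

An individual is a **species** with one or more behavioral states and a
row-stochastic transition matrix `P` (a Markov chain over states). Each
state has a turning-angle concentration `ρ ∈ [0, 1]`, a fixed maximum step
length `L`, and a perceptual range `R`. The landscape is a raster of
resistance values `r ∈ [0, 1]` (0 = free movement, 1 = impassable; no
raster = homogeneous space). Each simulated step:

1. draws the next state from `P`;
2. samples resistance along `K = 72` radial lines out to `R` and sums the
   conductances `1 − r` per line into an empirical angular distribution;
3. builds a discrete wrapped-normal turning kernel with mean resultant
   length `ρ`, centered on the previous heading;
4. multiplies the two distributions and draws the new heading from the
   product;
5. moves a distance `L · (1 − (r_start + r_end)/2)` along the drawn
   heading, never landing on an impassable cell.

Simulation runs at high temporal frequency so the walker responds to the
landscape quasi-continuously; tracks are then downsampled (every *m*-th
fix) to telemetry resolution for comparison with real data.

**Parameter approximation.** Because observed tracks are low-frequency,
the high-frequency parameters `(ρ_i, L_i, P)` are approximated
pattern-oriented-modelling style: candidate parameter vectors are
simulated, downsampled by *m*, and scored by the L1 distances between their
turning-angle and step-length histograms and the observed ones; the two
distances are minimized jointly with an in-repo **NSGA-II** (elitist
multi-objective genetic algorithm), yielding a Pareto front of plausible
parameter sets.

## Worked example

Recover the parameters of a known correlated random walk (ρ = 0.95,
L = 10) from a 10× downsampled track:

```python
import numpy as np
import statewalk as sw

truth = sw.Species((sw.state_crw(0.95, 10.0, 100.0),),
                   sw.make_transition_matrix([[0.0]]))
traj = sw.simulate(truth, 10_000, seed=11)          # high-frequency track
track = sw.sample_movement(traj, 10)                # telemetry-like, m=10
obs = np.column_stack([track.x, track.y])

template = sw.SpeciesModelTemplate.default(1, perceptual_range=100.0,
                                           max_step_length=50.0)
model = sw.MovementCalibration(obs, template, m=10)
results = model.fit(pop_size=100, n_generations=30, seed=5)
print(results.best_params, results.front_objectives[results.best_index])
```

prints

```
[0.95485529 9.90692243] [0.0980981 0.064    ]
```

i.e. the front member with the smallest summed distance has
`ρ̂ ≈ 0.955` and `L̂ ≈ 9.91` — the generating values up to sampling noise —
with turning-angle and step-length L1 distances of about 0.10 and 0.06
(0 = identical histograms, 2 = disjoint). `results.summary()` tabulates the
whole Pareto front; `results.to_csv()` exports the per-generation trace.

The same workflow is available from the shell:

```bash
statewalk fixtures --kind river_corridor --seed 1 --out river.asc
statewalk simulate --species sp.cfg --raster river.asc --steps 10000 \
          --start 1500 1500 --seed 42 --out traj.csv
statewalk resample --traj traj.csv --every 10 --raster river.asc --out stats.csv
statewalk adjust   --track stats.csv --m 10 --pop 100 --gens 50 --seed 7 \
          --out trace.csv
```

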