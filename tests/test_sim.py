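import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import statewalk as sw
from statewalk.sim import wrapped_normal_weights


def dense_wrapped_normal_mrl(rho, n=200_000):
    """Oracle: mean resultant length of the wrapped normal by dense numeric
    integration of its series density (should return rho itself)."""
    theta = np.linspace(-np.pi, np.pi, n, endpoint=False)
    dens = np.ones_like(theta)
    p = 1
    while rho > 0 and rho ** (p * p) >= 1e-14:
        dens += 2.0 * rho ** (p * p) * np.cos(p * theta)
        p += 1
    dens = np.maximum(dens, 0)
    dens /= dens.sum()
    return abs(np.sum(dens * np.exp(1j * theta)))


class TestTurningKernel:
    def test_zero_concentration_is_exactly_uniform(self, grid):
        k = sw.turning_kernel(1.234, 0.0, grid)
        assert np.array_equal(k.weights, np.full(72, 1 / 72))

    @pytest.mark.parametrize("rho", [0.5, 0.75, 0.95])
    def test_mean_resultant_length_matches_concentration(self, grid, rho):
        oracle = dense_wrapped_normal_mrl(rho)
        assert abs(oracle - rho) < 1e-3  # sanity on the oracle itself
        k = sw.turning_kernel(0.0, rho, grid)
        assert abs(k.mean_resultant_length() - rho) < 2e-3

    def test_concentration_one_is_point_mass_at_nearest_angle(self, grid):
        k = sw.turning_kernel(np.pi / 2 + 0.01, 1.0, grid)
        assert k.weights.max() == 1.0
        assert grid.angles[np.argmax(k.weights)] == pytest.approx(np.pi / 2)

    def test_kernel_is_symmetric_about_its_center(self, grid):
        w = wrapped_normal_weights(grid, 0.8, center=0.0)
        # weight at +k offsets equals weight at -k offsets
        assert np.allclose(w[1:], w[1:][::-1], atol=1e-15)

    def test_centering_is_a_pure_rotation_on_grid_angles(self, grid):
        base = wrapped_normal_weights(grid, 0.9, center=0.0)
        rotated = wrapped_normal_weights(grid, 0.9, center=grid.angles[10])
        assert np.allclose(rotated, np.roll(base, 10), atol=1e-12)


class TestPerception:
    def test_no_raster_gives_equal_weights(self, grid):
        d = sw.perception_distribution(None, (0, 0), 100.0, grid, samples_per_line=5)
        assert np.array_equal(d.weights, np.full(72, 5.0))

    def test_all_zero_raster_gives_uniform_weights(self, grid):
        r = sw.ResistanceRaster(np.zeros((50, 50)), 0, 0, 10)
        d = sw.perception_distribution(r, (250, 250), 100.0, grid, samples_per_line=10)
        assert np.allclose(d.weights, 10.0)

    def test_corridor_walker_sees_along_channel(self, grid, corridor_raster):
        # mid-channel of an east-west corridor: east/west lines cross only
        # conductance-1 water; north/south lines hit the banks immediately
        loc = (105.0, 45.0)
        d = sw.perception_distribution(corridor_raster, loc, 80.0, grid, samples_per_line=16)
        east, west = d.weights[0], d.weights[36]
        north, south = d.weights[18], d.weights[54]
        # oracle: direct sample enumeration along the four cardinal lines
        for k, w in [(0, east), (18, north), (36, west), (54, south)]:
            ang = grid.angles[k]
            expected = sum(
                1.0 - sw.resistance_at(
                    corridor_raster,
                    loc[0] + 80.0 * j / 16 * np.cos(ang),
                    loc[1] + 80.0 * j / 16 * np.sin(ang),
                )
                for j in range(1, 17)
            )
            assert w == pytest.approx(expected, abs=1e-12)
        assert east == 16.0 and west == 16.0
        assert east > 4 * north and west > 4 * south

    def test_enclosed_walker_gets_zero_weight_beyond_own_cell(self, grid):
        values = np.ones((5, 5))
        values[2, 2] = 0.0
        r = sw.ResistanceRaster(values, 0, 0, 10)
        # samples all land outside the central free cell
        d = sw.perception_distribution(r, (25, 25), 40.0, grid, samples_per_line=4)
        assert np.array_equal(d.weights, np.zeros(72))


class TestCombine:
    def test_uniform_empirical_returns_kernel(self, grid):
        kernel = sw.turning_kernel(0.3, 0.9, grid)
        uniform = sw.AngularDistribution(grid, np.full(72, 3.0))
        out = sw.combine(uniform, kernel)
        assert np.abs(out.weights - kernel.normalized().weights).max() < 1e-12

    def test_uniform_kernel_returns_normalized_empirical(self, grid):
        emp = sw.AngularDistribution(grid, np.arange(72, dtype=float))
        kernel = sw.turning_kernel(0.0, 0.0, grid)
        out = sw.combine(emp, kernel)
        assert np.abs(out.weights - emp.normalized().weights).max() < 1e-12

    def test_all_zero_product_falls_back_to_kernel(self, grid):
        emp = sw.AngularDistribution(grid, np.zeros(72))
        kernel = sw.turning_kernel(0.0, 0.5, grid)
        out = sw.combine(emp, kernel)
        assert np.allclose(out.weights, kernel.normalized().weights)

    @given(
        e=hnp.arrays(np.float64, 72, elements=st.floats(0, 10)),
        kseed=st.integers(0, 100),
    )
    def test_product_normalizes_and_preserves_zeros(self, e, kseed):
        grid = sw.AngularGrid(72)
        kw = np.random.default_rng(kseed).random(72)
        emp = sw.AngularDistribution(grid, e)
        ker = sw.AngularDistribution(grid, kw)
        out = sw.combine(emp, ker)
        assert abs(out.weights.sum() - 1.0) < 1e-12
        if (e * kw).sum() > 0:
            assert (out.weights[(e == 0) | (kw == 0)] == 0).all()


class TestDrawHeading:
    def test_point_mass_always_drawn(self, grid):
        w = np.zeros(72)
        w[18] = 1.0  # pi/2
        dist = sw.AngularDistribution(grid, w)
        rng = np.random.default_rng(0)
        assert all(sw.draw_heading(dist, rng) == pytest.approx(np.pi / 2) for _ in range(50))

    def test_uniform_frequencies_within_binomial_ci(self, grid):
        dist = sw.AngularDistribution(grid, np.ones(72))
        rng = np.random.default_rng(1)
        n = 100_000
        draws = np.array([sw.draw_heading(dist, rng) for _ in range(n)])
        counts = np.array([(draws == a).sum() for a in grid.angles])
        p = 1 / 72
        se = np.sqrt(p * (1 - p) * n)
        assert (np.abs(counts - n * p) < 4 * se).all()

    def test_seeded_draws_reproducible(self, grid):
        dist = sw.AngularDistribution(grid, np.random.default_rng(2).random(72))
        a = [sw.draw_heading(dist, np.random.default_rng(3)) for _ in range(10)]
        b = [sw.draw_heading(dist, np.random.default_rng(3)) for _ in range(10)]
        assert a != sorted(a) or True  # sequence content checked below
        assert a == b


class TestStepFraction:
    def test_linear_attenuation_rule(self):
        values = np.array([[0.0, 1.0]])
        r = sw.ResistanceRaster(values, 0.0, 0.0, 10.0)
        free, blocked = (5.0, 5.0), (15.0, 5.0)
        assert sw.step_fraction(r, free, free) == 1.0
        assert sw.step_fraction(r, blocked, blocked) == 0.0
        assert sw.step_fraction(r, free, blocked) == 0.5

    def test_no_raster_full_step(self):
        assert sw.step_fraction(None, (0, 0), (100, 0)) == 1.0


class TestAdvance:
    def test_homogeneous_space_full_displacement(self):
        state = sw.state_crw(0.9, 10.0, 100.0)
        x, y = sw.advance((0.0, 0.0), np.pi / 4, state, None)
        assert np.hypot(x, y) == pytest.approx(10.0)

    def test_resting_state_never_moves(self):
        state = sw.state_resting(100.0)
        assert sw.advance((3.0, 4.0), 1.0, state, None) == (3.0, 4.0)

    def test_guard_stops_before_impassable_cell(self):
        # start mid free cell, intended endpoint in a resistance-1 cell:
        # attenuation alone leaves the walker at half step, and the guard
        # must pull it back to the farthest passable quarter-cell point
        values = np.array([[0.0, 1.0]])
        r = sw.ResistanceRaster(values, 0.0, 0.0, 10.0)
        state = sw.state_rw(12.0, 100.0)
        x, y = sw.advance((5.0, 5.0), 0.0, state, r)
        assert y == 5.0
        # oracle: ray-march at cell_size/4 increments from the scaled endpoint
        d = 0.5 * 12.0
        while d > 0 and sw.resistance_at(r, 5.0 + d, 5.0) >= 1.0:
            d -= 10.0 / 4
        assert x == pytest.approx(5.0 + d)
        assert sw.resistance_at(r, x, y) < 1.0

    def test_guard_shortens_within_own_cell(self):
        # walker mid free cell surrounded by impassable cells: the guard
        # pulls the step back to the farthest quarter-cell point still
        # inside its own cell
        values = np.ones((3, 3))
        values[1, 1] = 0.5
        r = sw.ResistanceRaster(values, 0, 0, 2.0)
        state = sw.state_rw(50.0, 10.0)
        x, y = sw.advance((3.0, 3.0), 0.7, state, r)
        assert (x, y) != (3.0, 3.0)
        assert sw.resistance_at(r, x, y) < 1.0  # still in the free cell
        assert np.hypot(x - 3.0, y - 3.0) <= np.sqrt(2) * 2.0

    def test_guard_stays_put_when_no_march_point_is_passable(self):
        # start near its cell corner heading outward: every quarter-cell
        # march point lies on impassable cells, so the walker waits
        values = np.ones((3, 3))
        values[1, 1] = 0.5
        r = sw.ResistanceRaster(values, 0, 0, 2.0)
        state = sw.state_rw(50.0, 10.0)
        assert sw.advance((3.9, 3.9), np.pi / 4, state, r) == (3.9, 3.9)


class TestSimulate:
    def test_levy_like_setup_runs_to_completion(self, two_state_species, river_raster):
        # compound RW/CRW walker, step 10, range 200, switching 0.01 both
        # ways, 3000 steps, with and without a river raster
        free = sw.simulate(two_state_species, 3000, seed=1)
        assert len(free) == 3001
        start = sw.channel_start(river_raster)
        constrained = sw.simulate(two_state_species, 3000, raster=river_raster, start=start, seed=1)
        assert len(constrained) == 3001

    def test_homogeneous_step_lengths_are_the_maximum(self, crw_species):
        traj = sw.simulate(crw_species, 5000, seed=2)
        assert np.abs(traj.displacements() - 10.0).max() < 1e-9

    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.75, 0.95])
    def test_concentration_recovered_from_realized_angles(self, rho):
        sp = sw.Species((sw.state_crw(rho, 10, 100),), sw.make_transition_matrix([[0.0]]))
        traj = sw.simulate(sp, 50_000, seed=3)
        angles = sw.turning_angles(traj.x, traj.y)
        mrl = abs(np.mean(np.exp(1j * angles)))
        assert abs(mrl - rho) < 0.02

    def test_full_concentration_gives_straight_line(self):
        sp = sw.Species((sw.state_crw(1.0, 5, 100),), sw.make_transition_matrix([[0.0]]))
        traj = sw.simulate(sp, 100, start_heading=0.0, seed=4)
        assert np.allclose(traj.y, 0.0, atol=1e-9)
        assert np.allclose(np.diff(traj.x), 5.0)

    def test_resting_steps_freeze_position_and_heading(self):
        sp = sw.Species(
            (sw.state_crw(1.0, 5, 100), sw.state_resting(100)),
            sw.make_transition_matrix([[0, 0.2], [0.2, 0]]),
        )
        traj = sw.simulate(sp, 2000, start_heading=0.0, seed=5)
        resting = traj.state[1:] == 1
        d = traj.displacements()
        assert resting.any() and (~resting).any()
        assert (d[resting] == 0.0).all()
        # rho = 1 CRW resumed after rest continues straight: path stays on y=0
        assert np.allclose(traj.y, 0.0, atol=1e-9)

    def test_random_walk_msd_grows_linearly(self):
        # diffusion oracle: for a uniform-heading walk of constant step L,
        # E[R^2] after n steps is n L^2
        sp = sw.Species((sw.state_rw(10, 100),), sw.make_transition_matrix([[0.0]]))
        n, L, reps = 100, 10.0, 1000
        r2 = np.empty(reps)
        for i in range(reps):
            t = sw.simulate(sp, n, seed=1000 + i)
            r2[i] = t.x[-1] ** 2 + t.y[-1] ** 2
        expected = n * L * L
        se = r2.std(ddof=1) / np.sqrt(reps)
        assert abs(r2.mean() - expected) < 4 * se

    def test_aquatic_walker_confined_to_water(self, river_raster):
        aquatic = sw.Species(
            (sw.state_rw(10, 100), sw.state_crw(0.95, 10, 500)),
            sw.make_transition_matrix([[0, 0.01], [0.002, 0]]),
        )
        start = sw.channel_start(river_raster)
        traj = sw.simulate(aquatic, 5000, raster=river_raster, start=start, seed=6)
        res = sw.resistance_at(river_raster, traj.x, traj.y)
        assert (res == 0.0).all()

    def test_no_coordinate_leaves_the_extent(self):
        r = sw.ResistanceRaster(np.zeros((20, 20)), 0, 0, 10)
        sp = sw.Species((sw.state_rw(30, 50),), sw.make_transition_matrix([[0.0]]))
        traj = sw.simulate(sp, 3000, raster=r, start=(100, 100), seed=7)
        xmin, ymin, xmax, ymax = r.extent
        assert (traj.x >= xmin).all() and (traj.x <= xmax).all()
        assert (traj.y >= ymin).all() and (traj.y <= ymax).all()

    def test_identical_seeds_give_bit_identical_trajectories(self, two_state_species):
        a = sw.simulate(two_state_species, 1000, seed=8)
        b = sw.simulate(two_state_species, 1000, seed=8)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
        assert np.array_equal(a.state, b.state)

    @pytest.mark.parametrize("use_raster", [False, True])
    def test_python_and_numba_engines_bit_identical(
        self, two_state_species, river_raster, use_raster
    ):
        raster = river_raster if use_raster else None
        start = sw.channel_start(river_raster) if use_raster else (0.0, 0.0)
        a = sw.simulate(two_state_species, 300, raster=raster, start=start, seed=9, engine="numba")
        b = sw.simulate(two_state_species, 300, raster=raster, start=start, seed=9, engine="python")
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
        assert np.array_equal(a.state, b.state)
        assert a.n_trapped == b.n_trapped

    def test_invalid_inputs_rejected(self, crw_species, corridor_raster):
        with pytest.raises(ValueError, match="n_steps"):
            sw.simulate(crw_species, 0, seed=0)
        with pytest.raises(ValueError, match="impassable"):
            sw.simulate(crw_species, 10, raster=corridor_raster, start=(105.0, 85.0), seed=0)
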