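"""Unit and property tests for the population optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmvonet.optimizer import (
    OptimizerConfig,
    UniverseState,
    exchange_objects,
    gradient_scale,
    normalize_fitness,
    optimize,
    roulette_wheel_select,
    traveling_distance_rate,
    wormhole_probability,
    wormhole_update,
)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


class TestNormalizeFitness:
    @pytest.mark.parametrize(
        "fitness, expected",
        [
            ([3.0, 4.0], [0.6, 0.8]),
            ([0.0, 0.0, 0.0], [0.0, 0.0, 0.0]),
            ([5.0], [1.0]),
        ],
    )
    def test_examples(self, fitness, expected):
        np.testing.assert_allclose(normalize_fitness(np.array(fitness)), expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            normalize_fitness(np.array([1.0, np.inf]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=20,
        )
    )
    def test_unit_norm_property(self, values):
        f = np.array(values)
        out = normalize_fitness(f)
        if np.any(f != 0):
            assert np.isclose(np.linalg.norm(out), 1.0)
        else:
            np.testing.assert_array_equal(out, f)


class TestRouletteWheel:
    def test_dominant_mass(self):
        rng = np.random.default_rng(0)
        picks = {roulette_wheel_select(np.array([0.0, 0.0, 1.0]), rng)
                 for _ in range(200)}
        assert picks == {2}

    def test_equal_weights_uniform(self):
        rng = np.random.default_rng(1)
        n, draws = 4, 100_000
        counts = np.bincount(
            [roulette_wheel_select(np.zeros(n), rng) for _ in range(draws)],
            minlength=n,
        )
        # 3-sigma binomial band around draws/n
        sigma = np.sqrt(draws * (1 / n) * (1 - 1 / n))
        assert np.all(np.abs(counts - draws / n) < 3 * sigma)

    def test_negative_weights_shifted_mass(self):
        rng = np.random.default_rng(2)
        picks = [roulette_wheel_select(np.array([-0.9, -0.1]), rng)
                 for _ in range(2000)]
        # shifted masses are (s, 0.8+s): index 1 takes essentially all draws
        assert np.mean(np.array(picks) == 1) > 0.999

    def test_empty_weights_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            roulette_wheel_select(np.array([]), np.random.default_rng(0))


class TestSchedules:
    def test_wormhole_probability_endpoints_and_midpoint(self):
        cfg = OptimizerConfig(n=5, max_iter=100, p_min=0.5, p_max=1.0)
        assert wormhole_probability(0, cfg) == 0.5
        assert wormhole_probability(100, cfg) == 1.0
        assert wormhole_probability(50, cfg) == pytest.approx(0.75)

    def test_traveling_distance_rate_endpoints_and_midpoint(self):
        cfg = OptimizerConfig(n=5, max_iter=100, chi=6.0)
        assert traveling_distance_rate(0, cfg) == 1.0
        assert traveling_distance_rate(100, cfg) == 0.0
        assert traveling_distance_rate(50, cfg) == pytest.approx(
            1.0 - 0.5 ** (1 / 6), abs=1e-9
        )

    def test_monotonicity(self):
        cfg = OptimizerConfig(n=5, max_iter=200)
        pw = [wormhole_probability(m, cfg) for m in range(201)]
        vt = [traveling_distance_rate(m, cfg) for m in range(201)]
        assert np.all(np.diff(pw) >= 0)
        assert np.all(np.diff(vt) < 0)
        assert all(0.0 <= v <= 1.0 for v in vt)

    def test_iteration_out_of_range(self):
        cfg = OptimizerConfig(n=5, max_iter=10)
        with pytest.raises(ValueError):
            wormhole_probability(11, cfg)
        with pytest.raises(ValueError):
            traveling_distance_rate(-1, cfg)


class TestGradientScale:
    def test_alpha_zero_gives_ones(self):
        cfg = OptimizerConfig(n=5, alpha=0.0)
        S = gradient_scale(np.array([1.0, -2.0]), np.array([3.0, 4.0]),
                           np.array([1e-4, 1e-4]), cfg)
        np.testing.assert_array_equal(S, np.ones(2))

    def test_zero_numerator_gives_ones(self):
        cfg = OptimizerConfig(n=5, alpha=0.7, eps=0.0)
        x = np.array([0.3, -1.2, 5.0])
        S = gradient_scale(x, x, np.full(3, 5e-4), cfg)
        np.testing.assert_array_equal(S, np.ones(3))

    def test_hand_evaluation_1d(self):
        cfg = OptimizerConfig(n=5, alpha=0.7, eps=0.0)
        S = gradient_scale(np.array([0.001]), np.array([0.0]),
                           np.array([0.0005]), cfg)
        assert S[0] == pytest.approx(1.7)

    def test_saturation_bounds_scale(self):
        cfg = OptimizerConfig(n=5, alpha=0.7)
        S = gradient_scale(np.array([10.0]), np.array([-10.0]),
                           np.array([1e-6]), cfg)
        assert S[0] == pytest.approx(1.7)  # ratio saturates at +1

    def test_nonpositive_delta_x_error(self):
        cfg = OptimizerConfig(n=5)
        with pytest.raises(ValueError, match="positive"):
            gradient_scale(np.zeros(2), np.zeros(2), np.array([1e-4, 0.0]), cfg)


def make_state(positions, fitness, lb, ub, best=None, best_fitness=None):
    positions = np.asarray(positions, float)
    fitness = np.asarray(fitness, float)
    order = np.argsort(fitness, kind="stable")
    f_norm = normalize_fitness(fitness)
    if best is None:
        best = positions[order[0]].copy()
        best_fitness = float(fitness[order[0]])
    d = positions.shape[1]
    return UniverseState(
        positions=positions.copy(),
        fitness=fitness,
        normalized_fitness=f_norm,
        sorted_positions=positions[order].copy(),
        sorted_normalized_fitness=f_norm[order],
        best=np.asarray(best, float),
        best_fitness=best_fitness,
        worst=positions[order[-1]].copy(),
        lb=np.full(d, float(lb)),
        ub=np.full(d, float(ub)),
    )


class TestExchangeObjects:
    def test_low_normalized_fitness_keeps_objects(self):
        # fitness [0, 1]: row 0 has F=0, never fires; row 1 has F=1, always fires
        state = make_state([[1.0, 2.0], [3.0, 4.0]], [0.0, 1.0], -10, 10)
        out = exchange_objects(state, np.random.default_rng(3))
        np.testing.assert_array_equal(out.positions[0], [1.0, 2.0])
        # row 1 always replaced by a donor value from the sorted matrix
        assert all(v in (1.0, 2.0, 3.0, 4.0) for v in out.positions[1])

    def test_always_fires_replaces_from_donor_rows(self):
        # single dominant fitness: row with F_norm == 1 is fully overwritten,
        # and only by values already present in some universe's same column
        positions = [[1.0, 2.0], [5.0, 6.0], [9.0, 10.0]]
        state = make_state(positions, [0.0, 0.0, 1.0], -20, 20)
        out = exchange_objects(state, np.random.default_rng(4))
        col_values = np.asarray(positions)
        for j in range(2):
            assert out.positions[2, j] in col_values[:, j]

    def test_hand_trace_2x2(self):
        """Replay the exchange step-by-step with scalar draws."""
        positions = np.array([[0.5, -1.0], [2.0, 3.0]])
        fitness = np.array([1.0, 2.0])
        state = make_state(positions, fitness, -10, 10)
        seed = 11
        out = exchange_objects(state, np.random.default_rng(seed))

        rng = np.random.default_rng(seed)
        f_norm = fitness / np.linalg.norm(fitness)
        order = np.argsort(fitness)
        sorted_pos = positions[order]
        w = -f_norm[order]
        w = w - w.min() + 1e-12
        cum = np.cumsum(w) / np.sum(w)
        r1 = np.array([[rng.random() for _ in range(2)] for _ in range(2)])
        expect = positions.copy()
        for i in range(2):
            for j in range(2):
                if r1[i, j] < f_norm[i]:
                    k = int(np.searchsorted(cum, rng.random(), side="right"))
                    expect[i, j] = sorted_pos[k, j]
        np.testing.assert_array_equal(out.positions, expect)


class TestWormholeUpdate:
    def test_no_wormhole_leaves_state_unchanged(self):
        state = make_state([[1.0, 2.0], [3.0, 4.0]], [1.0, 2.0], -10, 10)
        cfg = OptimizerConfig(n=2, max_iter=10, p_min=0.0, p_max=0.0, alpha=0.0)
        before = state.positions.copy()
        out = wormhole_update(state, 5, cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(out.positions, before)

    def test_zero_travel_rate_lands_on_best(self):
        state = make_state([[1.0, 2.0], [3.0, 4.0]], [1.0, 2.0], -10, 10)
        cfg = OptimizerConfig(n=2, max_iter=10, p_min=1.0, p_max=1.0, alpha=0.0)
        out = wormhole_update(state, 10, cfg, np.random.default_rng(6))
        # v_T(M) = 0, every cell fires: all rows collapse onto x_best
        for row in out.positions:
            np.testing.assert_array_equal(row, state.best)

    def test_positions_stay_in_box(self):
        rng = np.random.default_rng(7)
        positions = rng.uniform(-1, 1, (6, 4))
        state = make_state(positions, rng.random(6), -1, 1)
        cfg = OptimizerConfig(n=6, max_iter=10, p_min=1.0, p_max=1.0, alpha=0.7)
        out = wormhole_update(state, 1, cfg, rng)
        assert np.all(out.positions >= -1.0) and np.all(out.positions <= 1.0)


class TestOptimize:
    def test_constant_objective_flat_history(self):
        cfg = OptimizerConfig(lb=-1.0, ub=1.0, n=5, max_iter=20, seed=0)
        res = optimize(lambda x: 3.5, cfg, d=3)
        assert res.best_fitness == 3.5
        np.testing.assert_array_equal(res.history, np.full(20, 3.5))

    def test_determinism(self):
        cfg = OptimizerConfig(lb=-5.0, ub=5.0, n=8, max_iter=30, seed=42)
        r1 = optimize(sphere, cfg, d=4)
        r2 = optimize(sphere, cfg, d=4)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)
        np.testing.assert_array_equal(r1.history, r2.history)
        assert r1.best_fitness == r2.best_fitness
        assert r1.evaluations == r2.evaluations == 8 * 31

    @pytest.mark.parametrize("alpha", [0.0, 0.7])
    def test_elitism_and_feasibility(self, alpha):
        seen = []

        def probe(x):
            seen.append(x.copy())
            return sphere(x)

        cfg = OptimizerConfig(lb=-5.0, ub=5.0, n=10, max_iter=50,
                              alpha=alpha, seed=3)
        res = optimize(probe, cfg, d=3)
        assert np.all(np.diff(res.history) <= 0)
        assert res.best_fitness == res.history[-1]
        allx = np.array(seen)
        assert np.all(allx >= -5.0) and np.all(allx <= 5.0)

    def test_non_finite_objective_becomes_worst(self):
        calls = {"k": 0}

        def sometimes_nan(x):
            calls["k"] += 1
            return np.nan if calls["k"] == 1 else sphere(x)

        cfg = OptimizerConfig(lb=-1.0, ub=1.0, n=4, max_iter=2, seed=0)
        with pytest.warns(RuntimeWarning, match="non-finite"):
            res = optimize(sometimes_nan, cfg, d=2)
        assert np.isfinite(res.best_fitness)

    def test_zero_iterations_returns_initial_best(self):
        cfg = OptimizerConfig(lb=-2.0, ub=2.0, n=6, max_iter=0, seed=9)
        res = optimize(sphere, cfg, d=3)
        assert res.history.size == 0
        assert res.best_fitness == pytest.approx(sphere(res.best_position))

    def test_trace_csv_written(self, tmp_path):
        path = tmp_path / "trace.csv"
        cfg = OptimizerConfig(lb=-1.0, ub=1.0, n=4, max_iter=5, seed=1)
        res = optimize(sphere, cfg, d=2, trace_path=path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "iteration,best_fitness"
        assert len(lines) == 6
        assert float(lines[-1].split(",")[1]) == res.best_fitness


class TestReductionToPlainMVO:
    def test_alpha_zero_matches_literal_reference(self, mvo_reference):
        """With no gradient term the hybrid replays literal MVO bitwise."""
        n, d, M = 5, 3, 10
        cfg = OptimizerConfig(lb=-4.0, ub=4.0, n=n, max_iter=M,
                              p_min=0.2, p_max=1.0, chi=6.0, alpha=0.0, seed=123)
        res = optimize(sphere, cfg, d=d)
        _, best_f, history = mvo_reference(
            sphere, lb=-4.0, ub=4.0, n=n, d=d, max_iter=M,
            p_min=0.2, p_max=1.0, chi=6.0, seed=123,
        )
        assert res.best_fitness == best_f
        np.testing.assert_array_equal(res.history, history)


def test_config_validation_errors():
    with pytest.raises(ValueError):
        OptimizerConfig(n=1)
    with pytest.raises(ValueError):
        OptimizerConfig(n=5, p_min=0.9, p_max=0.5)
    with pytest.raises(ValueError):
        OptimizerConfig(n=5, delta_x_interval=(0.0, 1e-3))
    with pytest.raises(ValueError):
        OptimizerConfig(n=5, chi=0.0)
    with pytest.raises(ValueError):
        OptimizerConfig(n=5, lb=1.0, ub=1.0).bounds(3)
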