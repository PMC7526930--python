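"""Fruit-fly optimizer: decision values, decoding, elitist search dynamics."""

import numpy as np
import pytest

from chrysopt.foa import (
    BoundsError,
    FOAConfig,
    decode_candidate,
    init_swarm,
    optimize,
    smell_decision_value,
    step,
)


class TestInit:
    def test_seeded_axes_are_reproducible(self):
        cfg = FOAConfig(dimensions=11)
        a = init_swarm(cfg, np.random.default_rng(7))
        b = init_swarm(cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(a.axis_x, b.axis_x)
        np.testing.assert_array_equal(a.axis_y, b.axis_y)

    def test_axes_within_init_interval_and_shape(self):
        cfg = FOAConfig(dimensions=11)
        s = init_swarm(cfg, np.random.default_rng(0))
        assert s.axis_x.shape == (11,)
        assert (0 <= s.axis_x).all() and (s.axis_x <= 1).all()
        assert s.generation == 0 and s.evaluations == 0

    def test_asymmetric_flight_range_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            FOAConfig(fr=(-5.0, 10.0))


class TestSmellDecisionValue:
    @pytest.mark.parametrize(
        "x,y,expected",
        [(3.0, 4.0, 0.2), (1.0, 0.0, 1.0), (10.0, 10.0, 1.0 / np.sqrt(200.0))],
    )
    def test_reciprocal_distance(self, x, y, expected):
        assert smell_decision_value(np.array(x), np.array(y)) == pytest.approx(expected)

    def test_origin_is_floored_not_infinite(self):
        s = smell_decision_value(np.array(0.0), np.array(0.0))
        assert np.isfinite(s) and s == pytest.approx(1e12)


class TestDecode:
    def test_linear_map_midpoint(self):
        out = decode_candidate(np.array([0.5]), [(0.0, 100.0)])
        assert out[0, 0] == pytest.approx(50.0)

    def test_decision_values_above_unit_distance_clamp(self):
        out = decode_candidate(np.array([1.7]), [(0.0, 10.0)])
        assert out[0, 0] == pytest.approx(10.0)

    def test_categorical_rounds_to_nearest_code(self):
        # s decoding to 2.6 over 5 strain codes -> code 3
        out = decode_candidate(np.array([0.65]), [(0.0, 4.0)], {0: 5})
        assert out[0, 0] == 3.0

    def test_inverted_bounds_rejected(self):
        with pytest.raises(BoundsError):
            decode_candidate(np.array([0.5]), [(1.0, 0.0)])


class TestStep:
    def test_flat_landscape_keeps_incumbent(self):
        cfg = FOAConfig(dimensions=2, sizepop=5)
        rng = np.random.default_rng(3)
        swarm = init_swarm(cfg, rng)
        swarm = step(swarm, lambda c: np.ones(len(c)), [(0, 1), (0, 1)], cfg, rng)
        first_best = swarm.best_smell
        for _ in range(10):
            swarm = step(swarm, lambda c: np.ones(len(c)), [(0, 1), (0, 1)], cfg, rng)
        assert swarm.best_smell == first_best == 1.0

    def test_argmax_moves_axis_to_best_fly(self):
        cfg = FOAConfig(dimensions=1, sizepop=2)
        rng = np.random.default_rng(5)
        swarm = init_swarm(cfg, rng)
        swarm = step(swarm, lambda c: np.array([1.0, 3.0]), [(0, 1)], cfg, rng)
        assert swarm.best_index == 1
        np.testing.assert_array_equal(swarm.axis_x, swarm.x[1])
        np.testing.assert_array_equal(swarm.axis_y, swarm.y[1])

    def test_non_finite_smell_excluded_from_argmax(self):
        cfg = FOAConfig(dimensions=1, sizepop=3)
        rng = np.random.default_rng(8)
        swarm = init_swarm(cfg, rng)

        def objective(c):
            return np.array([np.nan, 2.0, np.inf])

        swarm = step(swarm, objective, [(0, 1)], cfg, rng)
        assert swarm.best_index == 1
        assert swarm.best_smell == 2.0


class TestOptimize:
    def test_exact_evaluation_budget(self):
        cfg = FOAConfig(dimensions=2, seed=0)
        res = optimize(lambda c: -((c - 0.3) ** 2).sum(axis=1), [(0, 1), (0, 1)], config=cfg)
        assert res.evaluations == cfg.maxgen * cfg.sizepop == 1000
        assert len(res.history) == cfg.maxgen

    def test_elitist_history_non_decreasing(self):
        cfg = FOAConfig(dimensions=2, seed=1)
        res = optimize(lambda c: -((c - 0.3) ** 2).sum(axis=1), [(0, 1), (0, 1)], config=cfg)
        assert all(a <= b for a, b in zip(res.history, res.history[1:]))

    def test_deterministic_given_seed(self):
        cfg = FOAConfig(dimensions=2, seed=11)
        obj = lambda c: -((c - 0.5) ** 2).sum(axis=1)
        a = optimize(obj, [(0, 1), (0, 1)], config=cfg)
        b = optimize(obj, [(0, 1), (0, 1)], config=cfg)
        np.testing.assert_array_equal(a.best_inputs, b.best_inputs)
        assert a.history == b.history

    def test_scalar_parabola_is_solved(self):
        hits = 0
        for seed in range(20):
            cfg = FOAConfig(dimensions=1, seed=seed)
            res = optimize(lambda c: -((c[:, 0] - 0.5) ** 2), [(0, 1)], config=cfg)
            hits += res.best_predicted_efficiency > -1e-3
        assert hits >= 18

    def test_decoded_candidates_stay_within_bounds(self):
        bounds = [(0.0, 4.0), (2.0, 9.0), (-1.0, 1.0)]
        seen = []

        def objective(c):
            seen.append(c.copy())
            return -((c[:, 1] - 5.0) ** 2)

        cfg = FOAConfig(dimensions=3, maxgen=30, seed=2)
        optimize(objective, bounds, categorical_spec={0: 5}, config=cfg)
        allc = np.vstack(seen)
        for j, (lo, hi) in enumerate(bounds):
            assert (allc[:, j] >= lo).all() and (allc[:, j] <= hi).all()
        assert np.array_equal(allc[:, 0], np.rint(allc[:, 0]))  # valid codes

    def test_categorical_matches_exhaustive_enumeration(self):
        table = np.random.default_rng(123).uniform(0, 10, 6)
        best_code = int(np.argmax(table))
        hits = 0
        for seed in range(20):
            cfg = FOAConfig(dimensions=1, seed=seed)
            res = optimize(
                lambda c: table[c[:, 0].astype(int)],
                [(0.0, 5.0)],
                categorical_spec={0: 6},
                config=cfg,
            )
            hits += int(res.best_inputs[0]) == best_code
        assert hits >= 19
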