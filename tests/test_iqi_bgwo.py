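"""Quantum-inspired optimizer: gate algebra, decode pipeline, loop behavior."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qigwo.gwo_core import unit_bounds
from qigwo.iqi_bgwo import (
    IqiConfig,
    QubitVector,
    iqi_minimize,
    leader_theta,
    majority_vote,
    position_update,
    rotate_leader_qubit,
    sigmoid,
    sigmoid_binarize,
    threshold_binary,
    y_rotation_matrix,
)

angles = st.floats(min_value=-50.0, max_value=50.0, allow_nan=False)


class TestYRotationMatrix:
    def test_zero_angle_is_identity(self):
        assert y_rotation_matrix(0.0) == pytest.approx(np.eye(2))

    def test_quarter_turn(self):
        assert y_rotation_matrix(np.pi / 2) @ np.array([1.0, 0.0]) == pytest.approx(
            [0.0, 1.0], abs=1e-15
        )

    @given(theta=angles)
    def test_norm_preservation(self, theta):
        v = np.array([0.6, 0.8])
        assert np.linalg.norm(y_rotation_matrix(theta) @ v) == pytest.approx(1.0, abs=1e-12)

    @given(t1=angles, t2=angles)
    def test_composition_is_angle_addition(self, t1, t2):
        composed = y_rotation_matrix(t1) @ y_rotation_matrix(t2)
        assert composed == pytest.approx(y_rotation_matrix(t1 + t2), abs=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            y_rotation_matrix(float("inf"))


class TestLeaderTheta:
    def test_zero_when_leader_equals_wolf(self, rng):
        x = rng.random(5)
        assert leader_theta(x, x, zeta=1.3, gamma=0.7) == 0.0

    def test_zero_zeta(self, rng):
        assert leader_theta(rng.random(4), rng.random(4), zeta=0.0, gamma=0.9) == 0.0

    def test_hand_evaluated_angle(self):
        # difference sums to 0.5; zeta = pi/2, gamma = 0.5 -> pi^2/4
        leader = np.array([0.5, 0.25])
        wolf = np.array([0.0, 0.25])
        theta = leader_theta(leader, wolf, zeta=np.pi / 2, gamma=0.5)
        assert theta == pytest.approx(np.pi**2 / 4)
        assert theta == pytest.approx(2.4674, abs=1e-4)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            leader_theta(np.zeros(3), np.zeros(2), 1.0, 1.0)


class TestRotateLeaderQubit:
    def test_zero_angle_unchanged(self):
        q = np.array([0.6, 0.8])
        assert rotate_leader_qubit(q, 0.0) == pytest.approx(q)

    def test_equal_superposition_eighth_turn(self):
        q = np.array([1.0, 1.0]) / np.sqrt(2)
        assert rotate_leader_qubit(q, np.pi / 4) == pytest.approx([0.0, 1.0], abs=1e-15)

    def test_thousand_rotations_keep_unit_norm(self, rng):
        q = np.array([1.0, 0.0])
        for theta in rng.uniform(-np.pi, np.pi, 1000):
            q = rotate_leader_qubit(q, theta)
        assert q @ q == pytest.approx(1.0, abs=1e-9)

    def test_rejects_unnormalized_input(self):
        with pytest.raises(ValueError, match="normalized"):
            rotate_leader_qubit(np.array([0.5, 0.5]), 0.1)


class TestQubitVector:
    def test_unit_norm_enforced(self):
        with pytest.raises(ValueError):
            QubitVector(x=np.array([0.5]), y=np.array([0.5]))

    def test_rotation_drift_bounded(self, rng):
        q = QubitVector(x=np.full(8, 2**-0.5), y=np.full(8, 2**-0.5))
        for theta in rng.uniform(-np.pi, np.pi, 1000):
            q = q.rotate(float(theta))
        assert np.abs(q.x**2 + q.y**2 - 1.0).max() <= 1e-9
        assert np.all((q.y_squared >= 0) & (q.y_squared <= 1))


class TestDecodeOps:
    def test_position_update_arithmetic(self):
        assert position_update(np.array([0.8]), np.array([0.5]))[0] == pytest.approx(0.4)
        assert position_update(np.array([0.3, 0.7]), np.array([1.0, 0.0])) == pytest.approx(
            [0.3, 0.0]
        )

    @pytest.mark.parametrize(
        "pos,ysq,bit", [(0.5, 0.25, 1), (0.0, 0.0, 1), (0.1, 0.5, 0)]
    )
    def test_threshold_inclusive(self, pos, ysq, bit):
        assert threshold_binary(np.array([pos]), np.array([ysq]))[0] == bit

    @pytest.mark.parametrize(
        "a,b,d,expected",
        [((1,), (1,), (0,), 1), ((0,), (0,), (1,), 0), ((1,), (1,), (1,), 1), ((0,), (0,), (0,), 0)],
    )
    def test_majority_vote(self, a, b, d, expected):
        assert majority_vote(np.array(a), np.array(b), np.array(d))[0] == expected

    def test_majority_vote_order_invariant(self, rng):
        a, b, d = (rng.integers(0, 2, 16) for _ in range(3))
        base = majority_vote(a, b, d)
        for perm in ((b, a, d), (d, b, a), (b, d, a)):
            assert np.array_equal(majority_vote(*perm), base)

    def test_majority_vote_length_mismatch(self):
        with pytest.raises(ValueError):
            majority_vote(np.zeros(3), np.zeros(3), np.zeros(2))

    def test_sigmoid_values(self):
        assert sigmoid(0.0) == pytest.approx(0.5)
        assert sigmoid(1.0) == pytest.approx(0.7310585786300049, abs=1e-12)

    def test_sigmoid_binarize(self):
        assert sigmoid_binarize(np.array([0.0]), s=0.4)[0] == 1  # 0.5 >= 0.4
        assert sigmoid_binarize(np.array([0.0]), s=0.6)[0] == 0
        with pytest.raises(ValueError):
            sigmoid_binarize(np.array([0.0]), s=1.5)


class TestIqiConfig:
    def test_literal_half_amplitudes_renormalized(self):
        with pytest.warns(UserWarning, match="renormaliz"):
            cfg = IqiConfig(bounds=unit_bounds(3), amplitude_init=(0.5, 0.5))
        x0, y0 = cfg.amplitude_init
        assert x0**2 + y0**2 == pytest.approx(1.0)

    def test_s_threshold_validated(self):
        with pytest.raises(ValueError):
            IqiConfig(bounds=unit_bounds(2), s_threshold=1.5)


class TestIqiMinimize:
    def test_constant_objective(self):
        cfg = IqiConfig.binary(6, population_size=5, max_iterations=10, seed=0)
        res = iqi_minimize(lambda b: 7.5, cfg)
        assert res.best_fitness == 7.5
        assert res.optimal_iteration == 0
        assert set(np.unique(res.best_position)) <= {0, 1}

    def test_one_dimension_matches_exhaustive_argmin(self):
        for seed in range(5):
            table = {0: 0.4, 1: 0.1} if seed % 2 else {0: 0.05, 1: 0.8}
            cfg = IqiConfig.binary(1, population_size=4, max_iterations=20, seed=seed)
            res = iqi_minimize(lambda b: table[int(b[0])], cfg)
            assert res.best_fitness == min(table.values())

    def test_onemax_at_default_budget(self):
        def onemax(bits):
            return float(np.sum(bits == 0))

        hits = 0
        for seed in range(10):
            cfg = IqiConfig.binary(20, population_size=10, max_iterations=200, seed=seed)
            hits += iqi_minimize(onemax, cfg).best_fitness == 0
        assert hits >= 8

    def test_deterministic_and_non_increasing(self):
        def obj(bits):
            return float(np.sum(bits))

        cfg = IqiConfig.binary(12, population_size=6, max_iterations=40, seed=3)
        r1, r2 = iqi_minimize(obj, cfg), iqi_minimize(obj, cfg)
        assert np.array_equal(r1.trajectory, r2.trajectory)
        assert np.all(np.diff(r1.trajectory) <= 0)

    def test_elitism_reports_best_evaluated(self):
        evaluated = []

        def tracking(bits):
            v = float(np.sum(bits == 0) * 0.37 + np.sum(bits) * 0.11)
            evaluated.append(v)
            return v

        cfg = IqiConfig.binary(4, population_size=5, max_iterations=30, seed=8)
        res = iqi_minimize(tracking, cfg)
        assert res.best_fitness == min(evaluated)


class TestStationarityUnderZeroZeta:
    def test_qubit_and_thresholds_frozen(self):
        # zeta = 0 zeroes every rotation angle, so amplitudes (and with them
        # the decode thresholds y^2) never move
        q = QubitVector(x=np.full(4, 2**-0.5), y=np.full(4, 2**-0.5))
        start = q.y_squared.copy()
        for _ in range(100):
            theta = leader_theta(np.ones(4), np.zeros(4), zeta=0.0, gamma=0.8)
            q = q.rotate(theta)
        assert q.y_squared == pytest.approx(start, abs=1e-15)
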