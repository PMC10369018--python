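import cmath
import math

import numpy as np
import pandas as pd
import pytest

from steerevolve.analysis import (
    circular_mean,
    gaussian_small_angle_fit,
    inferred_rule_heatmap,
    near_wall_turn_signs,
    presence_density,
    segment_length_estimate,
    signed_turn_distribution,
    signed_turns,
    wall_following_fraction,
)
from steerevolve.config import fixture_avoider_brain
from steerevolve.geometry import ArenaConfig
from steerevolve.simulate import run_round
from steerevolve.wall_rule import EmpiricalRuleParams, empirical_turn

ARENA = ArenaConfig()


def make_trajectory(x, y, d_w, theta_w, delta_phi):
    n = len(x)
    return pd.DataFrame(
        {
            "time": np.arange(n),
            "x": x,
            "y": y,
            "heading": np.zeros(n),
            "d_w": d_w,
            "theta_w": theta_w,
            "delta_phi": delta_phi,
            "alive": True,
        }
    )


class TestCircularMean:
    def test_symmetric_pair(self):
        assert circular_mean([0.0, math.pi / 2]) == pytest.approx(math.pi / 4)

    def test_wraparound_pair_averages_to_pi(self):
        assert circular_mean([math.pi - 0.1, -math.pi + 0.1]) == pytest.approx(math.pi)

    def test_antipodal_pair_is_undefined(self):
        assert math.isnan(circular_mean([math.pi / 2, -math.pi / 2]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            circular_mean([])

    def test_matches_complex_argument_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            angles = rng.uniform(-math.pi, math.pi, rng.integers(1, 60))
            expected = cmath.phase(sum(cmath.exp(1j * a) for a in angles))
            assert circular_mean(angles) == pytest.approx(expected, abs=1e-12)


class TestInferredRuleHeatmap:
    def test_single_step_populates_single_bin(self):
        traj = make_trajectory([10.0], [10.0], [25.0], [0.7], [0.3])
        grid = inferred_rule_heatmap(traj, ARENA, n_angle=8, n_dist=5)
        assert grid.counts.sum() == 1
        assert np.nansum(grid.mean_turn) == pytest.approx(0.3)

    def test_zero_turn_trajectory_gives_zero_means(self):
        rng = np.random.default_rng(1)
        traj = make_trajectory(
            rng.uniform(0, 600, 500),
            rng.uniform(0, 600, 500),
            rng.uniform(0, 300, 500),
            rng.uniform(-math.pi, math.pi, 500),
            np.zeros(500),
        )
        grid = inferred_rule_heatmap(traj, ARENA, n_angle=6, n_dist=4)
        assert np.all(grid.mean_turn[grid.counts > 0] == 0.0)
        assert np.all(np.isnan(grid.mean_turn[grid.counts == 0]))

    def test_recovers_rule_signs_from_simulated_behaviour(self):
        # close the simulate -> infer loop: trajectories generated by the
        # rule-fitted brain must yield a heatmap with the rule's sign pattern
        brain = fixture_avoider_brain()
        rng = np.random.default_rng(2)
        arena = ArenaConfig(max_lifespan=400)
        trajs = [
            run_round(brain, arena, "explore", rng.uniform(20, 580, 2), rng.uniform(-3, 3)).trajectory
            for _ in range(100)
        ]
        grid = inferred_rule_heatmap(trajs, arena, n_angle=12, n_dist=10)
        rule = EmpiricalRuleParams(60.0)
        expected = empirical_turn(
            grid.angle_centers[:, None], np.broadcast_to(grid.distance_centers, (12, 10)), rule
        )
        strong = (grid.counts >= 50) & (np.abs(expected) > 0.1)
        assert strong.sum() >= 5
        assert np.all(np.sign(grid.mean_turn[strong]) == np.sign(expected[strong]))


class TestPresenceDensity:
    def test_mass_normalized(self):
        rng = np.random.default_rng(3)
        traj = make_trajectory(
            rng.uniform(0, 600, 200),
            rng.uniform(0, 600, 200),
            rng.uniform(0, 300, 200),
            rng.uniform(-math.pi, math.pi, 200),
            rng.uniform(-1, 1, 200),
        )
        density = presence_density(traj, ARENA)
        assert density.mean_turn.sum() == pytest.approx(1.0, abs=1e-9)

    def test_stationary_centre_record_fills_far_column(self):
        traj = make_trajectory([300.0] * 50, [300.0] * 50, [300.0] * 50, [0.1] * 50, [0.0] * 50)
        density = presence_density(traj, ARENA, n_dist=10)
        assert density.mean_turn[:, -1].sum() == pytest.approx(1.0)

    def test_wall_hugging_path_concentrates_near_wall(self):
        n = 300
        traj = make_trajectory(
            np.linspace(10, 590, n), np.full(n, 10.0), np.full(n, 10.0),
            np.full(n, math.pi / 2), np.zeros(n),
        )
        density = presence_density(traj, ARENA, n_dist=30)
        near = density.distance_centers < 50
        assert density.mean_turn[:, near].sum() >= 0.8


class TestSignedTurns:
    def test_turning_away_is_positive_by_definition(self):
        traj = make_trajectory(
            [0, 0, 0, 0], [0] * 4, [20.0] * 4,
            [0.5, -0.5, 1.0, -1.0], [0.3, -0.3, 0.8, -0.8],
        )
        assert np.all(signed_turns(traj, "near") > 0)

    def test_head_on_steps_contribute_zero(self):
        traj = make_trajectory([0, 0], [0, 0], [20.0, 20.0], [0.0, 0.0], [0.9, -0.9])
        assert np.all(signed_turns(traj, "near") == 0.0)

    def test_empty_regime_flagged(self):
        traj = make_trajectory([0], [0], [100.0], [0.5], [0.3])
        dist = signed_turn_distribution(traj, "far")
        assert dist.empty and dist.n_samples == 0

    def test_densities_integrate_to_one(self):
        rng = np.random.default_rng(4)
        traj = make_trajectory(
            rng.uniform(0, 600, 400), rng.uniform(0, 600, 400),
            rng.uniform(0, 49, 400), rng.uniform(-3, 3, 400),
            rng.uniform(-3, 3, 400),
        )
        dist = signed_turn_distribution(traj, "near")
        widths = np.diff(dist.bin_edges)
        assert np.sum(dist.densities * widths) == pytest.approx(1.0, abs=1e-9)


class TestGaussianSmallAngleFit:
    def test_parameter_recovery_on_synthetic_normal(self):
        rng = np.random.default_rng(5)
        sample = rng.normal(0.0, math.radians(10.0), 10_000)
        fit = gaussian_small_angle_fit(sample)
        assert abs(fit.mean) < math.radians(0.5)
        assert fit.sd == pytest.approx(math.radians(10.0), rel=0.05)
        assert fit.ks_distance < 0.05

    def test_degenerate_all_zero_sample(self):
        fit = gaussian_small_angle_fit(np.zeros(100))
        assert fit.degenerate and fit.sd == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            gaussian_small_angle_fit(np.zeros(10))


class TestSegmentLength:
    def test_one_step_oscillator(self):
        # forward 50 px, U-turn, back 50 px, repeat
        n = 20
        x = np.where(np.arange(n) % 2 == 0, 100.0, 150.0)
        traj = make_trajectory(x, np.zeros(n), np.full(n, 100.0), np.zeros(n), np.full(n, math.pi))
        assert segment_length_estimate(traj) == pytest.approx(50.0)

    def test_three_step_bouts(self):
        xs, turns = [], []
        x, direction = 100.0, 1.0
        for _ in range(8):
            for k in range(3):
                xs.append(x)
                turns.append(math.pi if k == 0 else 0.0)
                x += direction * 50.0
            direction *= -1.0
        traj = make_trajectory(np.array(xs), np.zeros(len(xs)), np.full(len(xs), 100.0),
                               np.zeros(len(xs)), np.array(turns))
        assert segment_length_estimate(traj) == pytest.approx(150.0)

    def test_straight_line_is_undefined(self):
        traj = make_trajectory(np.linspace(0, 500, 11), np.zeros(11), np.full(11, 100.0),
                               np.zeros(11), np.zeros(11))
        assert math.isnan(segment_length_estimate(traj))


class TestWallFollowing:
    def test_boundary_hugging_path(self):
        traj = make_trajectory(np.linspace(0, 600, 50), np.full(50, 10.0), np.full(50, 10.0),
                               np.zeros(50), np.zeros(50))
        assert wall_following_fraction(traj, band=100.0) == 1.0

    def test_centre_pinned_record(self):
        traj = make_trajectory([300.0] * 20, [300.0] * 20, [300.0] * 20, [0.0] * 20, [0.0] * 20)
        assert wall_following_fraction(traj, band=100.0) == 0.0


class TestNearWallTurnSigns:
    def test_antisymmetric_construction(self):
        traj = make_trajectory(
            [0] * 4, [0] * 4, [20.0] * 4, [0.5, 0.5, -0.5, -0.5], [0.4, 0.6, -0.4, -0.6]
        )
        right, left = near_wall_turn_signs(traj)
        assert right > 0 > left
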