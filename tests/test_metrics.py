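"""Step, turn, rest and step-distribution metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aquatrack.metrics import (
    StepSeries,
    fit_step_distribution,
    resting_fraction,
    step_lengths,
    stops_per_distance,
    turning_angles,
)
from aquatrack.synthetic import (
    CRWParams,
    ExponentialSteps,
    PowerLawSteps,
    generate_crw,
    rest_occupancy_params,
)
from aquatrack.trajectory import ArenaConfig, PathSegment


def segment_from_xy(xy):
    xy = np.asarray(xy, dtype=float)
    return PathSegment(np.arange(float(len(xy))), xy[:, 0], xy[:, 1])


BIG_ARENA = ArenaConfig(width_cm=100_000.0, height_cm=100_000.0)


class TestStepLengths:
    def test_three_four_five_triangle(self):
        seg = segment_from_xy([[0, 0], [3, 4]])
        s = step_lengths(seg)
        assert s.step_cm[0] == 5.0
        assert s.is_relocation[0]

    def test_identical_points_give_zero_resting_step(self):
        seg = segment_from_xy([[1, 1], [1, 1]])
        s = step_lengths(seg)
        assert s.step_cm[0] == 0.0
        assert not s.is_relocation[0]

    def test_matches_brute_force_pairwise_computation(self, rng):
        xy = rng.uniform(0, 50, (50, 2))
        s = step_lengths(segment_from_xy(xy))
        expected = [
            np.sqrt(((xy[i + 1] - xy[i]) ** 2).sum()) for i in range(49)
        ]
        np.testing.assert_allclose(s.step_cm, expected)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            step_lengths(segment_from_xy([[0, 0]]))

    @given(
        angle=st.floats(-np.pi, np.pi),
        tx=st.floats(-50, 50),
        ty=st.floats(-50, 50),
        scale=st.floats(0.1, 10.0),
    )
    def test_rigid_motion_invariance_and_scaling(self, angle, tx, ty, scale):
        rng = np.random.default_rng(99)
        xy = rng.uniform(0, 10, (20, 2))
        base = step_lengths(segment_from_xy(xy)).step_cm
        R = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = xy @ R.T + [tx, ty]
        np.testing.assert_allclose(
            step_lengths(segment_from_xy(moved)).step_cm, base, atol=1e-9
        )
        scaled = xy * scale
        np.testing.assert_allclose(
            step_lengths(segment_from_xy(scaled)).step_cm, base * scale,
            rtol=1e-9,
        )


class TestRestingFraction:
    def test_all_below_threshold_is_fully_resting(self):
        s = StepSeries(np.full(10, 0.05), np.zeros(10, bool))
        assert resting_fraction(s).resting_fraction == 1.0

    def test_alternating_steps_give_half(self):
        steps = np.tile([0.05, 1.0], 5)
        s = StepSeries(steps, steps >= 0.1)
        assert resting_fraction(s).resting_fraction == 0.5

    def test_tie_at_threshold_counts_as_relocation(self):
        s = StepSeries(np.array([0.1]), np.array([True]))
        assert resting_fraction(s).resting_fraction == 0.0

    def test_resting_and_moving_fractions_sum_to_one(self, rng):
        steps = rng.exponential(0.2, 500)
        s = StepSeries(steps, steps >= 0.1)
        r = resting_fraction(s).resting_fraction
        m = np.count_nonzero(steps >= 0.1) / 500
        assert r + m == 1.0

    def test_recovers_generator_occupancy(self):
        # power-law moving steps sit entirely above the threshold, so the
        # displacement classification tracks the true bout states
        params = rest_occupancy_params(
            0.4,
            n_steps=10_000,
            step_model=PowerLawSteps(mu=2.5, x_min_cm=0.2),
            arena=BIG_ARENA,
            start_xy_cm=(50_000.0, 50_000.0),
        )
        traj = generate_crw(params, 31)
        seg = segment_from_xy(traj.xy)
        frac = resting_fraction(step_lengths(seg)).resting_fraction
        p, q = params.p_move_to_rest, params.p_rest_to_move
        var = 0.4 * 0.6 * (2 - p - q) / ((p + q) * params.n_steps)
        assert abs(frac - 0.4) < 3 * np.sqrt(var)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            resting_fraction(StepSeries(np.array([]), np.array([], bool)))


class TestTurningAngles:
    def test_collinear_motion_has_zero_angles(self):
        seg = segment_from_xy([[0, 0], [1, 0], [2, 0], [3, 0]])
        np.testing.assert_allclose(turning_angles(seg).theta_deg, 0.0)

    def test_left_turn_is_plus_ninety(self):
        seg = segment_from_xy([[0, 0], [1, 0], [1, 1]])
        np.testing.assert_allclose(turning_angles(seg).theta_deg, [90.0])

    def test_reversal_maps_to_plus_180(self):
        seg = segment_from_xy([[0, 0], [1, 0], [0, 0]])
        np.testing.assert_allclose(turning_angles(seg).theta_deg, [180.0])

    def test_rest_breaks_the_chain(self):
        # relocation, tiny resting step, relocation: no angle across the rest
        seg = segment_from_xy([[0, 0], [1, 0], [1.0001, 0], [2, 1]])
        assert len(turning_angles(seg)) == 0

    def test_angles_within_open_closed_interval(self, rng):
        xy = rng.uniform(0, 100, (200, 2))
        th = turning_angles(segment_from_xy(xy)).theta_deg
        assert np.all(th > -180.0) and np.all(th <= 180.0)

    @given(angle=st.floats(-np.pi, np.pi), tx=st.floats(-30, 30))
    def test_invariance_under_rotation_and_translation(self, angle, tx):
        rng = np.random.default_rng(7)
        xy = rng.uniform(0, 10, (30, 2))
        base = turning_angles(segment_from_xy(xy)).theta_deg
        R = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = xy @ R.T + [tx, 0.0]
        np.testing.assert_allclose(
            turning_angles(segment_from_xy(moved)).theta_deg, base, atol=1e-9
        )

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            turning_angles(segment_from_xy([[0, 0], [1, 0]]))


class TestStopsPerDistance:
    def test_no_rests_means_zero_stops(self):
        steps = np.full(10, 1.0)
        assert stops_per_distance(StepSeries(steps, steps >= 0.1)) == 0.0

    def test_one_stop_over_half_metre(self):
        steps = np.array([20.0, 30.0, 0.01])
        s = StepSeries(steps, steps >= 0.1)
        assert stops_per_distance(s) == pytest.approx(2.0)

    def test_matches_brute_force_transition_count(self, rng):
        steps = rng.exponential(0.5, 1000)
        s = StepSeries(steps, steps >= 0.1)
        reloc = steps >= 0.1
        n_stops = sum(
            1 for i in range(999) if reloc[i] and not reloc[i + 1]
        )
        expected = n_stops / (steps[reloc].sum() / 100.0)
        assert stops_per_distance(s) == pytest.approx(expected)

    def test_zero_distance_rejected(self):
        steps = np.full(5, 0.01)
        with pytest.raises(ValueError):
            stops_per_distance(StepSeries(steps, steps >= 0.1))


class TestFitStepDistribution:
    def test_exponential_sample_classified_exponential(self, rng):
        x = rng.exponential(1.0, 10_000)
        fit = fit_step_distribution(x, x_min_cm=0.1)
        assert fit.verdict == "exponential"
        assert fit.aic_exponential < fit.aic_powerlaw

    def test_pareto_sample_classified_powerlaw(self, rng):
        x = 0.1 * (1 + rng.pareto(1.0, 10_000))  # mu = 2
        fit = fit_step_distribution(x, x_min_cm=0.1)
        assert fit.verdict == "powerlaw"
        assert abs(fit.mu - 2.0) < 0.1

    def test_small_sample_is_inconclusive(self, rng):
        x = rng.exponential(1.0, 30)
        assert fit_step_distribution(x, x_min_cm=0.01).verdict == "inconclusive"

    def test_no_steps_above_cutoff_rejected(self):
        with pytest.raises(ValueError):
            fit_step_distribution(np.array([0.01, 0.02]), x_min_cm=0.1)

    def test_classification_power_at_n_10k(self):
        # the verdict matches the generating model in >= 95% of replicates
        n_rep = 100
        correct = 0
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            xe = rng.exponential(0.5, 10_000)
            xp = 0.1 * (1 + rng.pareto(1.0, 10_000))
            ok_e = fit_step_distribution(xe, x_min_cm=0.1).verdict == "exponential"
            ok_p = fit_step_distribution(xp, x_min_cm=0.1).verdict == "powerlaw"
            correct += ok_e and ok_p
        assert correct >= 95
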