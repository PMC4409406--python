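"""Generator contracts: determinism, bout structure, closed-form moments."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aquatrack.synthetic import (
    CRWParams,
    ExponentialSteps,
    PowerLawSteps,
    SceneConfig,
    generate_brownian,
    generate_crw,
    generate_density_experiment,
    generate_reference_path,
    render_frames,
    rest_occupancy_params,
)
from aquatrack.trajectory import ArenaConfig


class TestCRW:
    def test_same_seed_reproduces_identical_trajectory(self):
        p = CRWParams(n_steps=500)
        a = generate_crw(p, 42)
        b = generate_crw(p, 42)
        np.testing.assert_array_equal(a.x_cm, b.x_cm)
        np.testing.assert_array_equal(a.y_cm, b.y_cm)
        np.testing.assert_array_equal(a.moving, b.moving)

    def test_different_seeds_differ(self):
        p = CRWParams(n_steps=200)
        a = generate_crw(p, 1)
        b = generate_crw(p, 2)
        assert not np.allclose(a.x_cm, b.x_cm)

    def test_absorbing_move_state_never_rests(self):
        p = CRWParams(n_steps=2000, p_move_to_rest=0.0)
        traj = generate_crw(p, 0)
        assert traj.moving.all()

    def test_rest_displacement_is_jitter_only(self):
        p = CRWParams(n_steps=2000, p_move_to_rest=0.5, p_rest_to_move=0.3,
                      jitter_sd_cm=0.0)
        traj = generate_crw(p, 3)
        d = np.hypot(np.diff(traj.x_cm), np.diff(traj.y_cm))
        assert np.all(d[~traj.moving] == 0.0)

    def test_huge_kappa_gives_collinear_path(self):
        p = CRWParams(
            n_steps=50, p_move_to_rest=0.0, turn_kappa=1e6, jitter_sd_cm=0.0,
            arena=ArenaConfig(width_cm=10000.0, height_cm=10000.0),
            start_xy_cm=(5000.0, 5000.0),
        )
        traj = generate_crw(p, 7)
        v = np.diff(np.column_stack([traj.x_cm, traj.y_cm]), axis=0)
        cross = v[:-1, 0] * v[1:, 1] - v[:-1, 1] * v[1:, 0]
        dot = (v[:-1] * v[1:]).sum(axis=1)
        turns = np.degrees(np.arctan2(cross, dot))
        assert np.max(np.abs(turns)) < 0.5

    def test_exponential_moving_step_mean_matches_closed_form(self):
        rate = 2.0
        p = CRWParams(
            n_steps=10_000, p_move_to_rest=0.0,
            step_model=ExponentialSteps(rate_per_cm=rate), jitter_sd_cm=0.0,
            arena=ArenaConfig(width_cm=100_000.0, height_cm=100_000.0),
            start_xy_cm=(50_000.0, 50_000.0),
        )
        traj = generate_crw(p, 11)
        steps = np.hypot(np.diff(traj.x_cm), np.diff(traj.y_cm))
        se = steps.std(ddof=1) / np.sqrt(len(steps))
        assert abs(steps.mean() - 1.0 / rate) < 3 * se

    def test_stationary_rest_occupancy_converges(self):
        # two-state chain: pi_rest = p / (p + q); n = 1e5, 3 SE tolerance
        # with the chain's autocorrelation inflating the variance by
        # (2 - p - q) / (p + q)
        p_mr, p_rm = 0.12, 0.18
        params = CRWParams(n_steps=100_000, p_move_to_rest=p_mr,
                           p_rest_to_move=p_rm)
        traj = generate_crw(params, 5)
        pi = params.stationary_rest_occupancy
        frac = 1.0 - traj.moving.mean()
        n = params.n_steps
        var = pi * (1 - pi) * (2 - p_mr - p_rm) / ((p_mr + p_rm) * n)
        assert abs(frac - pi) < 3 * np.sqrt(var)

    def test_walker_stays_inside_arena(self):
        arena = ArenaConfig(width_cm=30.0, height_cm=30.0, margin_cm=1.0)
        p = CRWParams(n_steps=5000, arena=arena, start_xy_cm=(15.0, 15.0),
                      jitter_sd_cm=0.0,
                      step_model=ExponentialSteps(rate_per_cm=0.5))
        traj = generate_crw(p, 9)
        assert traj.x_cm.min() >= 0 and traj.x_cm.max() <= 30
        assert traj.y_cm.min() >= 0 and traj.y_cm.max() <= 30

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"p_move_to_rest": 1.5}, "p_move_to_rest"),
            ({"p_rest_to_move": -0.1}, "p_rest_to_move"),
            ({"turn_kappa": -1.0}, "turn_kappa"),
            ({"jitter_sd_cm": -0.01}, "jitter_sd_cm"),
            ({"n_steps": 0}, "n_steps"),
            ({"start_xy_cm": (500.0, 50.0)}, "start_xy_cm"),
        ],
    )
    def test_invalid_params_rejected_with_field_name(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            CRWParams(**kwargs)

    @pytest.mark.parametrize(
        "model,field",
        [
            (lambda: ExponentialSteps(rate_per_cm=0.0), "rate_per_cm"),
            (lambda: PowerLawSteps(mu=1.0), "mu"),
            (lambda: PowerLawSteps(x_min_cm=0.0), "x_min_cm"),
        ],
    )
    def test_invalid_step_models_rejected(self, model, field):
        with pytest.raises(ValueError, match=field):
            model()


class TestBrownian:
    def test_zero_sd_keeps_all_points_identical(self):
        traj = generate_brownian(100, 0.0, 0)
        assert np.all(traj.x_cm == 0) and np.all(traj.y_cm == 0)

    def test_same_seed_identical(self):
        a = generate_brownian(500, 0.1, 8)
        b = generate_brownian(500, 0.1, 8)
        np.testing.assert_array_equal(a.xy, b.xy)

    def test_mean_squared_displacement_follows_diffusion_law(self):
        sd = 0.1
        traj = generate_brownian(100_000, sd, 13)
        xy = traj.xy
        for k in (10, 100):
            # non-overlapping windows give independent displacement samples
            d = xy[k::k] - xy[:-k:k][: len(xy[k::k])]
            msd = float((d**2).sum(axis=1).mean())
            expected = k * 2 * sd**2
            m = len(d)
            se = expected * np.sqrt(2.0 / (2 * m))  # chi2_2m relative error
            assert abs(msd - expected) < 5 * se

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            generate_brownian(1, 0.1, 0)


class TestReferencePaths:
    def test_straight_is_collinear_and_equally_spaced(self):
        traj = generate_reference_path("straight", 100.0, n_points=101)
        assert len(traj.xy) == 101
        steps = np.diff(traj.x_cm)
        np.testing.assert_allclose(steps, 1.0)
        assert np.all(traj.y_cm == 0)

    def test_koch_level1_has_four_thirds_segments(self):
        traj = generate_reference_path("koch", 90.0, level=1)
        seg = np.diff(traj.xy, axis=0)
        lengths = np.hypot(seg[:, 0], seg[:, 1])
        assert len(lengths) == 4
        np.testing.assert_allclose(lengths, 30.0)

    @given(level=st.integers(min_value=0, max_value=6))
    def test_koch_total_length_formula(self, level):
        extent = 100.0
        traj = generate_reference_path("koch", extent, level=level)
        seg = np.diff(traj.xy, axis=0)
        total = np.hypot(seg[:, 0], seg[:, 1]).sum()
        expected = extent * (4.0 / 3.0) ** level
        assert abs(total - expected) / expected < 1e-9

    def test_unsupported_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            generate_reference_path("spiral", 10.0)


class TestRenderFrames:
    def test_full_occlusion_leaves_only_background(self, small_arena):
        scene = SceneConfig(arena=small_arena, occlusion_prob=1.0,
                            background_sd=0.0)
        traj = generate_reference_path("straight", 10.0, n_points=5)
        traj.x_cm += 15.0
        traj.y_cm += 20.0
        frames = render_frames(traj, scene, 0)
        assert frames.frames.max() <= scene.background_mean + 1

    def test_noiseless_blob_argmax_at_true_position(self, small_arena):
        scene = SceneConfig(arena=small_arena, background_sd=0.0)
        traj = generate_reference_path("straight", 1.0, n_points=2)
        traj.x_cm[:] = 20.0
        traj.y_cm[:] = 20.0
        frames = render_frames(traj, scene, 0)
        r, c = np.unravel_index(np.argmax(frames.frames[0]), frames.frames[0].shape)
        H = frames.frames[0].shape[0]
        x = (c + 0.5) / scene.px_per_cm
        y = (H - r - 0.5) / scene.px_per_cm
        assert abs(x - 20.0) <= 1.0 / scene.px_per_cm
        assert abs(y - 20.0) <= 1.0 / scene.px_per_cm

    def test_occluded_fraction_matches_binomial(self, small_arena):
        scene = SceneConfig(arena=small_arena, occlusion_prob=0.3)
        n = 1000
        traj = generate_reference_path("straight", 1.0, n_points=n)
        traj.x_cm[:] = 20.0
        traj.y_cm[:] = 20.0
        frames = render_frames(traj, scene, 17)
        frac = frames.occluded.mean()
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(frac - 0.3) < 3 * se

    def test_point_outside_arena_rejected(self, small_arena):
        scene = SceneConfig(arena=small_arena)
        traj = generate_reference_path("straight", 100.0, n_points=11)
        with pytest.raises(ValueError, match="outside"):
            render_frames(traj, scene, 0)


class TestDensityExperiment:
    def test_tidy_output_with_labels(self):
        scenario = {
            "low": rest_occupancy_params(0.3, n_steps=50),
            "high": rest_occupancy_params(0.6, n_steps=50),
        }
        df = generate_density_experiment(scenario, 3, 0)
        assert set(df.columns) >= {"time_s", "x_cm", "y_cm", "individual_id",
                                   "treatment"}
        assert set(df["treatment"]) == {"low", "high"}
        assert df.groupby("treatment")["individual_id"].nunique().eq(3).all()

    def test_single_individual_per_treatment_rejected(self):
        scenario = {
            "a": rest_occupancy_params(0.3, n_steps=10),
            "b": rest_occupancy_params(0.3, n_steps=10),
        }
        with pytest.raises(ValueError, match="individuals"):
            generate_density_experiment(scenario, 1, 0)

    def test_single_treatment_rejected(self):
        with pytest.raises(ValueError, match="treatment"):
            generate_density_experiment(
                {"only": rest_occupancy_params(0.3, n_steps=10)}, 3, 0
            )

    def test_null_scenario_allowed(self):
        params = rest_occupancy_params(0.4, n_steps=30)
        df = generate_density_experiment({"a": params, "b": params}, 3, 1)
        assert df["treatment"].nunique() == 2
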