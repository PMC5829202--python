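"""Per-frame and per-trial behavioural measures."""

import numpy as np
import pytest

from shoalkit.metrics import (
    MetricsError,
    compute_centroid,
    compute_cohesion,
    compute_headings,
    compute_in_front,
    compute_polarization,
    compute_speeds,
    frame_metrics,
    split_foraging_trial,
    summarize_trial,
)
from shoalkit.trajectory import Circle, TrialMetadata

from .conftest import make_trajectory, translating_group


class TestCentroidAndCohesion:
    def test_coincident_and_midpoint(self):
        pos = np.tile([[10.0, -3.0]], (5, 5, 1))
        np.testing.assert_allclose(
            compute_centroid(make_trajectory(pos)), np.tile([10.0, -3.0], (5, 1))
        )
        two = np.tile([[[0.0, 0.0], [2.0, 0.0]]], (3, 1, 1))
        np.testing.assert_allclose(
            compute_centroid(make_trajectory(two)), np.tile([1.0, 0.0], (3, 1))
        )

    def test_residual_displacements_sum_to_zero(self, rng):
        pos = rng.normal(0.0, 100.0, (10, 5, 2))
        traj = make_trajectory(pos)
        resid = pos - compute_centroid(traj)[:, None, :]
        np.testing.assert_allclose(resid.sum(axis=1), 0.0, atol=1e-9)

    def test_cohesion_matches_brute_force(self, rng):
        pos = rng.normal(0.0, 80.0, (6, 5, 2))
        traj = make_trajectory(pos)
        d = compute_cohesion(traj)
        c = pos.mean(axis=1)
        for t in range(6):
            for i in range(5):
                assert d[t, i] == pytest.approx(
                    np.linalg.norm(pos[t, i] - c[t]) / 10.0
                )

    def test_two_fish_ten_cm_apart(self):
        pos = np.tile([[[0.0, 0.0], [100.0, 0.0]]], (3, 1, 1))
        np.testing.assert_allclose(compute_cohesion(make_trajectory(pos)), 5.0)


class TestSpeeds:
    def test_stationary_is_zero(self):
        pos = np.tile([[5.0, 5.0]], (10, 1, 1))
        np.testing.assert_allclose(compute_speeds(make_trajectory(pos)), 0.0)

    def test_one_mm_per_frame_at_24_fps_is_2_4_cm_s(self):
        pos = np.zeros((10, 1, 2))
        pos[:, 0, 0] = np.arange(10)  # 1 mm per frame
        np.testing.assert_allclose(compute_speeds(make_trajectory(pos)), 2.4)

    def test_circular_path_matches_chord_formula(self):
        r, dtheta, fps = 50.0, 0.1, 24.0
        t = np.arange(100)
        pos = np.stack(
            [r * np.cos(dtheta * t), r * np.sin(dtheta * t)], axis=-1
        )[:, None, :]
        speed = compute_speeds(make_trajectory(pos, fps=fps))
        expected = 2 * r * np.sin(dtheta / 2) * fps / 10.0  # cm/s
        np.testing.assert_allclose(speed, expected, rtol=1e-9)

    def test_frame_dropping_leaves_speed_unchanged_on_smooth_path(self):
        pos = np.zeros((40, 1, 2))
        pos[:, 0, 0] = 2.0 * np.arange(40)
        full = compute_speeds(make_trajectory(pos, fps=24.0))
        half = compute_speeds(make_trajectory(pos[::2], fps=12.0))
        np.testing.assert_allclose(half, full[0, 0], rtol=1e-12)


class TestHeadings:
    def test_straight_motion(self):
        pos = np.zeros((10, 1, 2))
        pos[:, 0, 0] = np.arange(10.0)
        h = compute_headings(make_trajectory(pos))
        np.testing.assert_allclose(h[:, 0], np.tile([1.0, 0.0], (10, 1)))

    def test_jitter_below_min_step_carries_forward(self):
        pos = np.zeros((10, 1, 2))
        pos[:5, 0, 0] = np.arange(5.0)            # moving +x
        pos[5:, 0, 0] = 4.0 + 0.05 * (np.arange(5) % 2)  # sub-threshold jitter
        h = compute_headings(make_trajectory(pos), min_step=0.2)
        np.testing.assert_allclose(h[:, 0], np.tile([1.0, 0.0], (10, 1)))

    def test_undefined_until_first_valid_step(self):
        pos = np.zeros((6, 1, 2))
        pos[3:, 0, 1] = np.arange(3.0)
        h = compute_headings(make_trajectory(pos), min_step=0.2)
        assert np.isnan(h[:3, 0]).all()
        np.testing.assert_allclose(h[3:, 0], np.tile([0.0, 1.0], (3, 1)))

    def test_circle_heading_is_near_tangent(self):
        r, dtheta = 100.0, 0.05
        t = np.arange(60)
        pos = np.stack(
            [r * np.cos(dtheta * t), r * np.sin(dtheta * t)], axis=-1
        )[:, None, :]
        h = compute_headings(make_trajectory(pos))
        tangent = np.stack(
            [-np.sin(dtheta * t), np.cos(dtheta * t)], axis=-1
        )
        # displacement direction lags the analytic tangent by half a step
        dots = (h[:-1, 0] * tangent[:-1]).sum(axis=1)
        assert np.all(dots > np.cos(dtheta))


class TestPolarization:
    def test_aligned_opposed_and_third(self):
        aligned = np.tile([1.0, 0.0], (1, 5, 1))
        assert compute_polarization(aligned)[0] == pytest.approx(1.0)
        opposed = np.array([[[1.0, 0.0], [-1.0, 0.0]]])
        assert compute_polarization(opposed)[0] == pytest.approx(0.0, abs=1e-12)
        three = np.array([[[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]]])
        assert compute_polarization(three)[0] == pytest.approx(1.0 / 3.0)

    def test_bounds_and_relabelling_invariance(self, rng):
        ang = rng.uniform(0, 2 * np.pi, (20, 5))
        h = np.stack([np.cos(ang), np.sin(ang)], axis=-1)
        p = compute_polarization(h)
        assert np.all((p >= 0) & (p <= 1))
        perm = rng.permutation(5)
        np.testing.assert_allclose(compute_polarization(h[:, perm]), p)

    def test_undefined_below_two_headings(self):
        h = np.full((3, 2, 2), np.nan)
        h[:, 0] = [1.0, 0.0]
        assert np.isnan(compute_polarization(h)).all()


class TestInFront:
    def test_fish_ahead_of_translating_group(self):
        offsets = [[10.0, 0.0], [-10.0, 0.0], [0.0, 5.0], [0.0, -5.0]]
        traj = translating_group(offsets, velocity=(10.0, 0.0))
        front = compute_in_front(traj)
        assert np.all(front[:, 0] == 1.0)
        assert np.all(front[:, 1] == 0.0)

    def test_fish_exactly_at_centroid_is_not_in_front(self):
        offsets = [[0.0, 0.0], [10.0, 0.0], [-10.0, 0.0]]
        traj = translating_group(offsets, velocity=(10.0, 0.0))
        front = compute_in_front(traj)
        assert np.all(front[:, 0] == 0.0)  # strict > 0 tie rule

    def test_stationary_group_is_undefined(self):
        traj = translating_group([[10.0, 0.0], [-10.0, 0.0]], velocity=(0.0, 0.0))
        assert np.isnan(compute_in_front(traj)).all()


class TestInvariance:
    def test_metrics_invariant_under_rotation_and_translation(self, rng):
        pos = rng.normal(0.0, 50.0, (30, 5, 2)).cumsum(axis=0) / 3 + rng.normal(
            0.0, 40.0, (1, 5, 2)
        )
        traj = make_trajectory(pos)
        theta = 1.1
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = make_trajectory(pos @ rot.T + np.array([100.0, -50.0]))
        np.testing.assert_allclose(
            compute_speeds(moved), compute_speeds(traj), atol=1e-9
        )
        np.testing.assert_allclose(
            compute_cohesion(moved), compute_cohesion(traj), atol=1e-9
        )
        p0 = compute_polarization(compute_headings(traj))
        p1 = compute_polarization(compute_headings(moved))
        np.testing.assert_allclose(p1, p0, atol=1e-9, equal_nan=True)
        np.testing.assert_allclose(
            compute_in_front(moved), compute_in_front(traj), atol=1e-9,
            equal_nan=True,
        )


class TestSummarizeTrial:
    def test_persistent_leader_structure(self):
        offsets = [[20.0, 0.0], [2.0, 1.0], [-2.0, -1.0], [1.0, 2.0], [-20.0, 0.0]]
        traj = translating_group(offsets, velocity=(10.0, 0.0), n_frames=24)
        tm = summarize_trial(traj)
        assert tm.front_proportion[0] == 1.0
        assert tm.front_proportion[4] == 0.0
        assert tm.leadership_variance > 0

    def test_leadership_variance_hand_example(self):
        # one constant leader, one constant trailer, three fish alternating
        # sides of the centroid -> front proportions (1, .5, .5, .5, 0),
        # population variance 0.1
        n_frames = 8
        base = 10.0 * np.arange(n_frames)
        alt = np.where(np.arange(n_frames) % 2 == 0, 2.0, -2.0)
        x = np.stack([base + 20.0, base + alt, base - alt, base + alt, base - 20.0], axis=1)
        pos = np.stack([x, np.zeros_like(x)], axis=-1)
        tm = summarize_trial(make_trajectory(pos))
        np.testing.assert_allclose(
            np.sort(tm.front_proportion), [0.0, 0.5, 0.5, 0.5, 1.0]
        )
        assert tm.leadership_variance == pytest.approx(0.1)

    def test_leadership_variance_matches_population_variance(self):
        offsets = [[20.0, 0.0], [5.0, 0.0], [0.0, 3.0], [-5.0, 0.0], [-20.0, 0.0]]
        traj = translating_group(offsets, velocity=(8.0, 2.0), n_frames=30)
        tm = summarize_trial(traj)
        assert tm.leadership_variance == pytest.approx(np.var(tm.front_proportion))

    def test_cover_occupancy_statistics(self):
        offsets = [[200.0, 0.0], [210.0, 0.0], [0.0, 0.0], [205.0, 5.0], [195.0, -5.0]]
        traj = translating_group(offsets, velocity=(0.0, 10.0), n_frames=8)
        meta = TrialMetadata(
            trial_id="t1", group_id="g", context="cover", trial_number=1,
            arena=Circle((0.0, 0.0), 400.0), cover=Circle((0.0, 0.0), 75.0),
        )
        tm = summarize_trial(traj, meta)
        assert tm.mean_n_out_of_cover == pytest.approx(4.0)
        assert tm.prop_all_out == pytest.approx(0.0)

    def test_empty_window_and_stationary_group_raise(self):
        traj = translating_group([[10.0, 0.0], [-10.0, 0.0]], n_frames=10)
        with pytest.raises(MetricsError, match="window"):
            summarize_trial(traj, frame_window=(5, 5))
        still = translating_group(
            [[10.0, 0.0], [-10.0, 0.0]], velocity=(0.0, 0.0), n_frames=10
        )
        with pytest.raises(MetricsError, match="front"):
            summarize_trial(still)


class TestForagingSplit:
    def _meta(self, depletion):
        return TrialMetadata(
            trial_id="t1", group_id="g", context="foraging", trial_number=1,
            arena=Circle((0.0, 0.0), 400.0), depletion_frame=depletion,
        )

    def test_split_windows(self):
        traj = translating_group([[0.0, 0.0], [5.0, 0.0]], n_frames=7200)
        pre, post = split_foraging_trial(traj, self._meta(1200))
        assert pre == (0, 1200) and post == (1200, 7200)

    def test_depletion_at_zero_gives_empty_pre_window(self):
        traj = translating_group([[0.0, 0.0], [5.0, 0.0]], n_frames=100)
        pre, post = split_foraging_trial(traj, self._meta(0))
        assert pre == (0, 0)
        with pytest.raises(MetricsError):
            summarize_trial(traj, self._meta(0), pre)

    def test_depletion_outside_trial_raises(self):
        traj = translating_group([[0.0, 0.0], [5.0, 0.0]], n_frames=100)
        with pytest.raises(MetricsError, match="outside"):
            split_foraging_trial(traj, self._meta(500))


def test_frame_metrics_bundles_consistent_series(open_meta, rng):
    pos = rng.normal(0.0, 30.0, (25, 5, 2)).cumsum(axis=0)
    traj = make_trajectory(pos)
    fm = frame_metrics(traj, open_meta)
    assert fm.centroid.shape == (25, 2)
    assert fm.individual_speed.shape == (25, 5)
    assert fm.n_out_of_cover is None
    defined = ~np.isnan(fm.polarization)
    assert np.all((fm.polarization[defined] >= 0) & (fm.polarization[defined] <= 1))
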