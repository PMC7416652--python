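import numpy as np
import pandas as pd
import pytest

from mocap3d import (StrikeMetrics, aggregate_trials, capacity_estimate,
                     fit_plane, fit_velocity_curve, interpoint_errors,
                     marker_board, mask_by_velocity, smooth_trajectory,
                     stationary_deviation, strike_metrics, velocity_profile)
from mocap3d.datasets import strike_trials
from mocap3d.triangulation import Trajectory3D


def traj_from_positions(pos, frame_rate_hz=750.0, valid=None):
    pos = np.asarray(pos, dtype=float)
    T, M, _ = pos.shape
    if valid is None:
        valid = np.ones((T, M), dtype=bool)
    return Trajectory3D(pos.copy(), valid, frame_rate_hz, list(range(M)))


def board_trajectory(T=100, noise=0.0, seed=0):
    board, ref = marker_board("small")
    rng = np.random.default_rng(seed)
    pos = np.tile(board, (T, 1, 1)) + rng.normal(0, noise, (T, 5, 3))
    return traj_from_positions(pos), ref


class TestInterpointErrors:
    def test_exact_geometry_gives_zero_errors(self):
        traj, ref = board_trajectory(T=10)
        errors, summary = interpoint_errors(traj, ref)
        assert np.allclose(errors["error_mm"], 0.0, atol=1e-12)
        assert np.allclose(summary["mean_abs"], 0.0, atol=1e-12)

    def test_corner_to_midpoint_reference_distance(self):
        _, ref = board_trajectory()
        # markers are numbered 1..5 in the reference geometry; pair (1,3)
        # is corner to edge-midpoint
        assert ref[0, 2] == pytest.approx(80.5, abs=0.05)

    def test_error_grows_with_noise(self):
        means = []
        for sigma in (0.1, 0.5, 1.0):
            traj, ref = board_trajectory(T=400, noise=sigma, seed=1)
            _, summary = interpoint_errors(traj, ref)
            means.append(summary["mean_abs"].mean())
        assert means[0] < means[1] < means[2]

    def test_asymmetric_reference_rejected(self):
        traj, ref = board_trajectory()
        bad = ref.copy()
        bad[0, 1] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            interpoint_errors(traj, bad)


class TestFitPlane:
    def test_exact_plane_zero_rms_unit_normal(self):
        pts = np.array([[0, 0, 5], [1, 0, 5], [0, 1, 5], [2, 3, 5],
                        [-1, 2, 5]], dtype=float)
        fit = fit_plane(pts)
        assert fit.rms_distance == pytest.approx(0.0, abs=1e-12)
        assert abs(fit.normal[2]) == pytest.approx(1.0)

    def test_single_outlier_bounded_by_epsilon(self):
        eps = 0.01
        pts = np.array([[0, 0, 5], [1, 0, 5], [0, 1, 5], [2, 3, 5],
                        [-1, 2, 5], [1, 1, 5 + eps]], dtype=float)
        assert fit_plane(pts).rms_distance <= eps

    def test_normal_recovered_under_noise(self):
        rng = np.random.default_rng(3)
        n = np.array([1.0, 2.0, -0.5])
        n /= np.linalg.norm(n)
        basis = np.linalg.svd(n[None, :])[2][1:]
        coords = rng.uniform(-50, 50, (50, 2))
        pts = coords @ basis + rng.normal(0, 0.2, (50, 3))
        fit = fit_plane(pts)
        assert abs(fit.normal @ n) >= 0.999

    def test_rigid_motion_leaves_distances_unchanged(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(4)
        pts = rng.uniform(-30, 30, (20, 3))
        pts[:, 2] = 0.2 * pts[:, 0] - 0.1 * pts[:, 1] + rng.normal(0, 1, 20)
        R = Rotation.from_rotvec([0.5, -0.2, 0.9]).as_matrix()
        t = np.array([100.0, -50.0, 30.0])
        d1 = fit_plane(pts).per_point_distance
        d2 = fit_plane(pts @ R.T + t).per_point_distance
        assert np.allclose(np.sort(d1), np.sort(d2), atol=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            fit_plane(pts)


class TestStationaryDeviation:
    def test_constant_trajectory_all_zero(self):
        traj = traj_from_positions(np.ones((50, 2, 3)))
        dev = stationary_deviation(traj)
        assert all(np.allclose(d, 0.0) for d in dev.values())

    def test_two_frame_midpoint_symmetry(self):
        pos = np.zeros((2, 1, 3))
        pos[1, 0, 0] = 2.0
        dev = stationary_deviation(traj_from_positions(pos))
        assert np.allclose(dev[0], [1.0, 1.0])

    def test_rms_matches_chi_moment_for_isotropic_noise(self):
        # 3D isotropic sigma: E[d^2] = 3 sigma^2, so RMS ~ sigma*sqrt(3)
        rng = np.random.default_rng(5)
        pos = rng.normal(0, 1.0, (6000, 1, 3))
        dev = stationary_deviation(traj_from_positions(pos))[0]
        rms = np.sqrt(np.mean(dev ** 2))
        assert rms == pytest.approx(np.sqrt(3.0), rel=0.15)

    def test_invalid_frames_rejected(self):
        valid = np.ones((10, 1), dtype=bool)
        valid[3] = False
        traj = traj_from_positions(np.zeros((10, 1, 3)), valid=valid)
        with pytest.raises(ValueError):
            stationary_deviation(traj)


class TestSmoothing:
    def test_noiseless_linear_motion_unchanged(self):
        t = np.arange(200.0)
        pos = np.stack([2.0 * t, -1.0 * t, 0.5 * t], axis=-1)[:, None, :]
        traj = traj_from_positions(pos)
        sm = smooth_trajectory(traj, q=0.01, r=1.0)
        assert np.max(np.abs(sm.positions - traj.positions)) < 1e-6

    def test_variance_reduction_on_stationary_noise(self):
        rng = np.random.default_rng(6)
        pos = rng.normal(0, 1.0, (6000, 1, 3))
        traj = traj_from_positions(pos)
        sm = smooth_trajectory(traj, q=0.01, r=1.0)
        for ax in range(3):
            assert sm.positions[:, 0, ax].var() < pos[:, 0, ax].var()

    def test_smoothing_shrinks_interpoint_error_iqr(self):
        traj, ref = board_trajectory(T=2000, noise=1.0, seed=7)
        _, raw = interpoint_errors(traj, ref)
        _, smo = interpoint_errors(smooth_trajectory(traj, q=0.01, r=1.0),
                                   ref)
        assert smo["iqr"].mean() < raw["iqr"].mean()

    def test_invalid_frames_bridged_but_still_flagged(self):
        t = np.arange(100.0)
        pos = np.stack([t, t, t], axis=-1)[:, None, :]
        valid = np.ones((100, 1), dtype=bool)
        valid[40:45] = False
        pos[40:45] = np.nan
        traj = traj_from_positions(pos, valid=valid)
        sm = smooth_trajectory(traj, q=0.01, r=1.0)
        assert not sm.valid[40:45].any()
        assert np.all(np.isfinite(sm.positions[40:45]))


class TestVelocity:
    def test_stationary_marker_zero_speed(self):
        traj = traj_from_positions(np.ones((20, 1, 3)))
        speeds, valid = velocity_profile(traj, 0)
        assert np.allclose(speeds[1:], 0.0) and valid[1:].all()
        assert not valid[0]

    def test_uniform_motion_2mm_per_frame_at_750hz(self):
        pos = np.zeros((30, 1, 3))
        pos[:, 0, 0] = 2.0 * np.arange(30)
        speeds, _ = velocity_profile(traj_from_positions(pos), 0)
        assert np.allclose(speeds[1:], 1.5)

    def test_frame_count_to_elapsed_time(self):
        # 86 steps at 750 Hz span 114.7 ms
        assert 86 / 750.0 * 1000.0 == pytest.approx(114.7, abs=0.05)

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            velocity_profile(traj_from_positions(np.ones((5, 1, 3))), 9)


class TestMaskByVelocity:
    def test_all_below_threshold_keeps_everything(self):
        speeds = np.array([np.nan, 1.0, 2.0, 1.5])
        assert mask_by_velocity(speeds, threshold=2.5).all()

    def test_teleported_sample_dropped_neighbors_kept(self):
        # one sample displaced 10 mm -> both incident steps at 7.5 m/s
        pos = np.zeros((10, 1, 3))
        pos[:, 0, 0] = np.arange(10) * 0.1
        pos[5, 0, 0] += 10.0
        traj = traj_from_positions(pos)
        speeds, valid = velocity_profile(traj, 0)
        keep = mask_by_velocity(speeds, valid, threshold=2.5)
        assert not keep[5]
        assert keep[4] and keep[6]
        assert keep.sum() == 9

    def test_infinite_threshold_is_identity(self):
        rng = np.random.default_rng(8)
        speeds = np.concatenate([[np.nan], rng.uniform(0, 100, 19)])
        assert mask_by_velocity(speeds, threshold=np.inf).all()

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            mask_by_velocity(np.array([np.nan, 1.0]), threshold=0.0)


class TestStrikeMetrics:
    def test_straight_line_strike_arithmetic(self):
        # 0.15 m over 0.1 s at 750 Hz: 75 steps of 2 mm
        pos = np.zeros((76, 1, 3))
        pos[:, 0, 0] = 2.0 * np.arange(76)
        traj = traj_from_positions(pos)
        sm = strike_metrics(traj, 0, (0, 75))
        assert sm.duration == pytest.approx(0.1)
        assert sm.path_distance == pytest.approx(0.15)
        assert sm.mean_speed == pytest.approx(1.5)
        assert sm.max_velocity >= 1.5 - 1e-12

    def test_identity_mean_speed_times_duration_is_path(self):
        rng = np.random.default_rng(9)
        pos = np.cumsum(rng.normal(0, 0.5, (50, 1, 3)), axis=0)
        traj = traj_from_positions(pos)
        sm = strike_metrics(traj, 0, (5, 45), threshold=np.inf)
        assert sm.mean_speed * sm.duration == pytest.approx(sm.path_distance,
                                                            rel=1e-12)

    def test_zero_length_window_rejected(self):
        traj = traj_from_positions(np.zeros((10, 1, 3)))
        with pytest.raises(ValueError):
            strike_metrics(traj, 0, (4, 4))


class TestAggregateTrials:
    def test_single_trial_is_its_own_mean(self):
        m = StrikeMetrics(0.1, 0.15, 1.5, 2.0)
        per_group, overall = aggregate_trials([m], grouping=["a"])
        assert overall["speed_ms"] == pytest.approx(1.5)
        assert per_group.loc[0, "max_velocity_ms"] == pytest.approx(2.0)

    def test_reference_trial_table_means(self):
        df = strike_trials()
        assert len(df) == 15
        per_group, overall = aggregate_trials(df, grouping=df["subject"])
        assert overall["duration_s"] == pytest.approx(0.1396109378, abs=5e-10)
        assert overall["distance_m"] == pytest.approx(0.1522, abs=5e-5)
        assert overall["speed_ms"] == pytest.approx(1.1208, abs=5e-5)
        assert overall["max_velocity_ms"] == pytest.approx(1.6376, abs=5e-5)
        assert set(per_group["subject"]) == {"Y4", "Y2", "B5"}

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            aggregate_trials([])


class TestVelocityCurve:
    def test_exact_quadratic_recovered(self):
        t = np.arange(30.0)
        v = 0.1 * t ** 2 - 0.4 * t + 2.0
        coeffs, fitted = fit_velocity_curve(v, degree=2)
        assert np.max(np.abs(fitted - v)) < 1e-9

    def test_degree_zero_is_mean(self):
        v = np.array([1.0, 2.0, 3.0, 6.0])
        coeffs, fitted = fit_velocity_curve(v, degree=0)
        assert coeffs[0] == pytest.approx(3.0)

    def test_pooled_fit_of_identical_trials_matches_single(self):
        t = np.arange(40.0)
        v = np.sin(t / 10) + 1.5
        c1, _ = fit_velocity_curve(v, degree=4)
        c2, _ = fit_velocity_curve([v, v.copy()], degree=4)
        assert np.allclose(c1, c2, atol=1e-9)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_velocity_curve(np.array([1.0, 2.0]), degree=4)


class TestCapacityEstimate:
    def test_one_second_rgb8_five_cameras(self):
        # five 640x480 RGB8 cameras at 750 Hz for 1 s
        assert capacity_estimate(5, 640, 480, 3, 750, 1) == 3_456_000_000

    def test_ten_seconds_bayer_bg8(self):
        # Bayer BG8 is 1 byte/px: a third of RGB8
        assert capacity_estimate(5, 640, 480, 1, 750, 10) == 11_520_000_000

    def test_zero_argument_gives_zero(self):
        assert capacity_estimate(0, 640, 480, 3, 750, 1) == 0
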