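from itertools import permutations

import numpy as np
import pytest

from mocap3d import (Detection, DetectionSet, InitialLabeling, KalmanTrack,
                     assign_hungarian, corrupt_detections,
                     get_correspondence, kf_predict, kf_update,
                     register_correspondence, track_markers,
                     snap_labeling, validate_correspondence_output)
from mocap3d.tracking import (MEASURED, PREDICTED, TrackingParams, TrackSet,
                              PluginValidationError)

from conftest import labeling_from_index


def _det(u, v):
    return Detection((float(u), float(v)), 25,
                     (int(u) - 2, int(v) - 2, int(u) + 3, int(v) + 3))


class TestKalman:
    def test_predict_is_linear_extrapolation(self):
        tr = KalmanTrack.start(0, 0, (100.0, 100.0), TrackingParams())
        tr.x = np.array([100.0, 100.0, 2.0, -1.0])
        pred, _ = kf_predict(tr)
        assert pred == pytest.approx((102.0, 99.0))

    def test_zero_velocity_prediction_stays_put(self):
        tr = KalmanTrack.start(0, 0, (50.0, 60.0), TrackingParams())
        pred, _ = kf_predict(tr)
        assert pred == pytest.approx((50.0, 60.0))

    def test_covariance_trace_grows_under_prediction(self):
        tr = KalmanTrack.start(0, 0, (0.0, 0.0), TrackingParams(q=1.0))
        before = np.trace(tr.P)
        kf_predict(tr)
        assert np.trace(tr.P) > before

    def test_tiny_measurement_noise_snaps_to_measurement(self):
        tr = KalmanTrack.start(0, 0, (0.0, 0.0), TrackingParams(r=1.0))
        kf_predict(tr)
        kf_update(tr, (10.0, -4.0), r=1e-12)
        assert tr.x[:2] == pytest.approx((10.0, -4.0), abs=1e-6)

    def test_huge_measurement_noise_keeps_prior(self):
        tr = KalmanTrack.start(0, 0, (5.0, 5.0), TrackingParams())
        prior = tr.x.copy()
        kf_update(tr, (100.0, 100.0), r=1e15)
        assert tr.x[:2] == pytest.approx(prior[:2], abs=1e-6)

    def test_repeated_updates_contract_toward_measurement(self):
        tr = KalmanTrack.start(0, 0, (0.0, 0.0), TrackingParams(q=0.1, r=1.0))
        target = np.array([20.0, 20.0])
        dists = []
        for _ in range(15):
            kf_update(tr, target)
            dists.append(np.linalg.norm(tr.x[:2] - target))
        assert all(b <= a + 1e-12 for a, b in zip(dists, dists[1:]))
        assert dists[-1] < dists[0] / 5

    def test_non_finite_measurement_rejected(self):
        tr = KalmanTrack.start(0, 0, (0.0, 0.0), TrackingParams())
        with pytest.raises(ValueError):
            kf_update(tr, (np.inf, 0.0))


def brute_force_assignment(cost):
    """Independent oracle: exhaustive search over permutations."""
    n, k = cost.shape
    best, best_cost = None, np.inf
    if n <= k:
        for perm in permutations(range(k), n):
            c = sum(cost[i, j] for i, j in enumerate(perm))
            if c < best_cost:
                best_cost = c
                best = list(enumerate(perm))
    else:
        for perm in permutations(range(n), k):
            c = sum(cost[i, j] for j, i in enumerate(perm))
            if c < best_cost:
                best_cost = c
                best = [(i, j) for j, i in enumerate(perm)]
    return best, best_cost


class TestHungarian:
    def test_single_entry(self):
        pairs, total = assign_hungarian(np.array([[7.0]]))
        assert pairs == [(0, 0)] and total == 7.0

    def test_two_by_two_both_permutations(self):
        pairs, total = assign_hungarian(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert pairs == [(0, 0), (1, 1)] and total == 2.0

    def test_empty_matrix(self):
        assert assign_hungarian(np.empty((0, 0))) == ([], 0.0)

    def test_infinite_cost_rejected(self):
        with pytest.raises(ValueError):
            assign_hungarian(np.array([[np.inf]]))

    @pytest.mark.parametrize("shape", [(6, 6), (4, 6), (6, 3)])
    def test_matches_exhaustive_oracle(self, shape):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            cost = rng.integers(0, 50, size=shape).astype(float)
            _, total = assign_hungarian(cost)
            _, oracle_total = brute_force_assignment(cost)
            assert total == pytest.approx(oracle_total)


class TestTrackMarkers:
    def test_noiseless_scene_zero_identity_swaps(self, noiseless_strike):
        scene, ds, lab = noiseless_strike
        ts = track_markers(ds, lab)
        for cam in range(len(scene.rig)):
            truth_px = scene.truth_pixels[cam]
            for m in range(scene.n_markers):
                pos = ts.positions[(cam, m)]
                st = ts.status[(cam, m)]
                assert all(s == MEASURED for s in st)
                assert np.allclose(pos, truth_px[:, m, :], atol=1e-9)

    def test_measured_positions_bit_identical_to_centroids(
            self, noiseless_strike):
        scene, ds, lab = noiseless_strike
        ts = track_markers(ds, lab)
        t, cam = 5, 1
        cents = {d.centroid for d in ds.get(t, cam)}
        for m in range(scene.n_markers):
            if ts.status[(cam, m)][t] == MEASURED:
                assert tuple(ts.positions[(cam, m)][t]) in cents

    def test_deterministic_given_same_inputs(self, noiseless_strike):
        _, ds, lab = noiseless_strike
        a = track_markers(ds, lab).to_dataframe()
        b = track_markers(ds, lab).to_dataframe()
        assert a.equals(b)

    def test_crossing_markers_with_wide_separation_keep_labels(self):
        # two markers pass each other, closest approach > 2*gate
        T = 40
        ds = DetectionSet(T, 1)
        for t in range(T):
            a = _det(10.0 + 5.0 * t, 100.0)
            b = _det(200.0 - 5.0 * t, 145.0)  # 45 px vertical separation
            ds.set(t, 0, [a, b] if t % 2 == 0 else [b, a])
        lab = InitialLabeling(t0=0, assignments={0: {0: 0, 1: 1}})
        ts = track_markers(ds, lab, gate=20.0)
        assert ts.positions[(0, 0)][-1] == pytest.approx((205.0, 100.0))
        assert ts.positions[(0, 1)][-1] == pytest.approx((5.0, 145.0))

    def test_occlusion_coasts_then_recaptures_same_label(self):
        T = 40
        ds = DetectionSet(T, 1)
        for t in range(T):
            dets = [_det(10.0 + 2.0 * t, 50.0)]
            if not (10 <= t <= 20):
                dets.append(_det(10.0 + 2.0 * t, 120.0))
            ds.set(t, 0, dets)
        lab = InitialLabeling(t0=0, assignments={0: {0: 0, 1: 1}})
        ts = track_markers(ds, lab, gate=30.0)
        st = ts.status[(0, 1)]
        assert all(s == PREDICTED for s in st[10:21])
        assert all(s == MEASURED for s in st[21:])
        assert ts.positions[(0, 1)][-1] == pytest.approx((10.0 + 2.0 * 39,
                                                          120.0))

    def test_backward_pass_tracks_frames_before_t0(self, noiseless_strike):
        scene, ds, index_lab = noiseless_strike
        _, index = corrupt_detections(scene.truth_pixels, 0.0, 0.0, seed=11)
        t0 = 10
        lab = labeling_from_index(index, t0, range(len(scene.rig)))
        ts = track_markers(ds, lab)
        truth_px = scene.truth_pixels[0]
        for m in range(scene.n_markers):
            assert np.allclose(ts.positions[(0, m)][:t0], truth_px[:t0, m],
                               atol=1e-9)

    def test_bad_detection_index_rejected(self, noiseless_strike):
        _, ds, _ = noiseless_strike
        lab = InitialLabeling(t0=0, assignments={0: {0: 99}})
        with pytest.raises(ValueError, match="99"):
            track_markers(ds, lab)


class TestSnapLabeling:
    def test_clicks_snap_to_nearest_detection(self, noiseless_strike):
        scene, ds, exact = noiseless_strike
        clicks = {}
        rng = np.random.default_rng(8)
        for cam, m in exact.assignments.items():
            clicks[cam] = {}
            for lab, idx in m.items():
                u, v = ds.get(0, cam)[idx].centroid
                clicks[cam][lab] = (u + rng.uniform(-2, 2),
                                    v + rng.uniform(-2, 2))
        snapped = snap_labeling(ds, 0, clicks)
        assert snapped.assignments == exact.assignments


class TestPluginContract:
    def test_builtin_resolves_by_name_and_matches_direct_call(
            self, noiseless_strike):
        _, ds, lab = noiseless_strike
        fn = get_correspondence("kalman_hungarian")
        assert fn(ds, lab).to_dataframe().equals(
            track_markers(ds, lab).to_dataframe())

    def test_identity_plugin_passes_validation(self, noiseless_strike):
        scene, ds, lab = noiseless_strike

        def identity_plugin(detections, labeling, **params):
            T = detections.n_timesteps
            cams = sorted(labeling.assignments)
            ts = TrackSet(T, cams, labeling.labels())
            for cam, m in labeling.assignments.items():
                for label, idx in m.items():
                    c = detections.get(labeling.t0, cam)[idx].centroid
                    for t in range(T):
                        ts.positions[(cam, label)][t] = c
                        ts.status[(cam, label)][t] = MEASURED
            return ts

        register_correspondence("identity", identity_plugin)
        out = get_correspondence("identity")(ds, lab)
        validate_correspondence_output(out)

    def test_duplicate_label_rejected_with_timestep(self):
        ts = TrackSet(8, [0], [0, 1])
        for t in range(8):
            for lab in (0, 1):
                ts.positions[(0, lab)][t] = (float(lab * 10), 5.0)
                ts.status[(0, lab)][t] = MEASURED
        ts.positions[(0, 1)][5] = ts.positions[(0, 0)][5]  # collision at t=5
        with pytest.raises(PluginValidationError, match="t=5"):
            validate_correspondence_output(ts)

    def test_unknown_engine_name_lists_registered(self):
        with pytest.raises(KeyError, match="kalman_hungarian"):
            get_correspondence("no_such_engine")
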