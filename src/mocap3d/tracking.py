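"""Marker identity maintenance per camera: Kalman prediction + Hungarian assignment.

Correspondence across cameras is carried entirely by a shared label space
fixed by a user-supplied labeling at one timestep; within each camera a
constant-velocity Kalman filter predicts every labeled marker one frame
ahead and the Hungarian algorithm matches predictions to detections.  The
filter only supports assignment: measured track positions are always the
raw detection centroids, never the filter mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detection import Detection, DetectionSet

__all__ = [
    "InitialLabeling",
    "KalmanTrack",
    "TrackSet",
    "TrackingParams",
    "kf_predict",
    "kf_update",
    "assign_hungarian",
    "track_markers",
    "snap_labeling",
    "register_correspondence",
    "get_correspondence",
    "validate_correspondence_output",
    "PluginValidationError",
]

# status codes per timestep
MEASURED = "measured"
PREDICTED = "predicted"
LOST = "lost"
ABSENT = "absent"  # before a track exists in a camera / label not present

_F = np.array([[1.0, 0, 1, 0],
               [0, 1, 0, 1],
               [0, 0, 1, 0],
               [0, 0, 0, 1]])
_H = np.array([[1.0, 0, 0, 0],
               [0, 1, 0, 0]])
# discrete white-acceleration process noise for Δt = 1, per axis blocks
_G = np.array([[0.25, 0, 0.5, 0],
               [0, 0.25, 0, 0.5],
               [0.5, 0, 1.0, 0],
               [0, 0.5, 0, 1.0]])


@dataclass
class TrackingParams:
    """Gating and noise parameters of the tracker.

    gate: max prediction→detection distance (px) for an assignment.
    q: process-noise intensity (px²/frame³); r: measurement noise (px²).
    max_coast: consecutive predicted frames before a track is marked lost.
    """

    gate: float = 30.0
    q: float = 1.0
    r: float = 1.0
    max_coast: int = 15


@dataclass
class InitialLabeling:
    """User-provided marker labels at one timestep.

    ``assignments[camera]`` maps label → detection index at ``t0`` (labels
    not visible in a camera are simply omitted).
    """

    t0: int
    assignments: dict[int, dict[int, int]]

    def labels(self) -> list[int]:
        labs: set[int] = set()
        for m in self.assignments.values():
            labs.update(m.keys())
        return sorted(labs)

    def validate(self, *, min_cameras: int = 2) -> None:
        for cam, m in self.assignments.items():
            idxs = list(m.values())
            if len(idxs) != len(set(idxs)):
                raise ValueError(
                    f"camera {cam}: a detection index is used by two labels"
                )
        for lab in self.labels():
            n_vis = sum(lab in m for m in self.assignments.values())
            if n_vis < min_cameras:
                raise ValueError(
                    f"label {lab} visible in {n_vis} camera(s) at t0; "
                    f"need >= {min_cameras} for triangulation"
                )


@dataclass
class KalmanTrack:
    """Constant-velocity track of one marker label in one camera.

    State is ``(u, v, du, dv)`` in px and px/frame.  ``positions[t]`` holds
    the reported position at each timestep: the raw detection centroid when
    ``status[t] == "measured"``, otherwise the filter prediction.
    """

    label: int
    camera: int
    x: np.ndarray
    P: np.ndarray
    params: TrackingParams = field(default_factory=TrackingParams)
    coast: int = 0

    @classmethod
    def start(cls, label: int, camera: int, position, params: TrackingParams
              ) -> "KalmanTrack":
        x = np.array([position[0], position[1], 0.0, 0.0])
        r = params.r
        P = np.diag([r, r, 100.0 * r, 100.0 * r])
        return cls(label, camera, x, P, params)


def kf_predict(track: KalmanTrack) -> tuple[np.ndarray, np.ndarray]:
    """Advance the track one frame; returns predicted (u, v) and covariance."""
    track.x = _F @ track.x
    track.P = _F @ track.P @ _F.T + track.params.q * _G
    return track.x[:2].copy(), (_H @ track.P @ _H.T).copy()


def kf_update(track: KalmanTrack, measurement, r: float | None = None
              ) -> np.ndarray:
    """Standard Kalman measurement update observing (u, v)."""
    z = np.asarray(measurement, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("measurement must be finite")
    rr = track.params.r if r is None else r
    S = _H @ track.P @ _H.T + rr * np.eye(2)
    K = track.P @ _H.T @ np.linalg.inv(S)
    track.x = track.x + K @ (z - _H @ track.x)
    track.P = (np.eye(4) - K @ _H) @ track.P
    track.P = 0.5 * (track.P + track.P.T)
    return track.x.copy()


_SENTINEL = 1e12


def assign_hungarian(cost: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Minimum-total-cost assignment of ``min(N, K)`` row–column pairs.

    Costs must be finite; encode disallowed pairings with a large sentinel.
    Returns pairs sorted by row index and the total assigned cost.
    """
    c = np.asarray(cost, dtype=float)
    if c.size == 0:
        return [], 0.0
    if c.ndim != 2:
        raise ValueError("cost must be a 2-D matrix")
    if not np.all(np.isfinite(c)):
        raise ValueError("cost matrix entries must be finite")
    rows, cols = linear_sum_assignment(c)
    pairs = sorted(zip(rows.tolist(), cols.tolist()))
    total = float(c[rows, cols].sum())
    return pairs, total


class TrackSet:
    """Labeled per-camera 2D trajectories over ``T`` timesteps."""

    def __init__(self, n_timesteps: int, cameras: Sequence[int],
                 labels: Sequence[int]):
        self.n_timesteps = int(n_timesteps)
        self.cameras = list(cameras)
        self.labels = list(labels)
        self.positions: dict[tuple[int, int], np.ndarray] = {}
        self.status: dict[tuple[int, int], np.ndarray] = {}
        for cam in self.cameras:
            for lab in self.labels:
                self.positions[(cam, lab)] = np.full((self.n_timesteps, 2), np.nan)
                self.status[(cam, lab)] = np.full(self.n_timesteps, ABSENT,
                                                  dtype=object)

    def measured_at(self, t: int, label: int) -> dict[int, np.ndarray]:
        """Camera → (u, v) for cameras where this label was measured at t."""
        out = {}
        for cam in self.cameras:
            if self.status[(cam, label)][t] == MEASURED:
                out[cam] = self.positions[(cam, label)][t]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in range(self.n_timesteps):
            for cam in self.cameras:
                for lab in self.labels:
                    st = self.status[(cam, lab)][t]
                    if st == ABSENT:
                        continue
                    u, v = self.positions[(cam, lab)][t]
                    rows.append({"t": t, "camera": cam, "label": lab,
                                 "u": u, "v": v, "status": st})
        return pd.DataFrame(rows, columns=["t", "camera", "label", "u", "v",
                                           "status"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrackSet":
        T = int(df["t"].max()) + 1 if len(df) else 0
        cams = sorted(df["camera"].unique().tolist())
        labs = sorted(df["label"].unique().tolist())
        ts = cls(T, cams, labs)
        for _, r in df.iterrows():
            key = (int(r["camera"]), int(r["label"]))
            t = int(r["t"])
            ts.positions[key][t] = (float(r["u"]), float(r["v"]))
            ts.status[key][t] = str(r["status"])
        return ts

    @classmethod
    def from_csv(cls, path) -> "TrackSet":
        return cls.from_dataframe(pd.read_csv(path, float_precision="round_trip"))


def _track_direction(
    detections: DetectionSet,
    labeling: InitialLabeling,
    params: TrackingParams,
    timesteps: Sequence[int],
    trackset: TrackSet,
) -> None:
    """Run the tracker over ``timesteps`` (already ordered away from t0)."""
    t0 = labeling.t0
    for cam, lab_map in labeling.assignments.items():
        dets0 = detections.get(t0, cam)
        tracks: dict[int, KalmanTrack] = {}
        for lab, det_idx in lab_map.items():
            c = dets0[det_idx].centroid
            tracks[lab] = KalmanTrack.start(lab, cam, c, params)
            trackset.positions[(cam, lab)][t0] = c
            trackset.status[(cam, lab)][t0] = MEASURED
        order = sorted(tracks)
        for t in timesteps:
            dets = detections.get(t, cam)
            preds = {}
            for lab in order:
                preds[lab], _ = kf_predict(tracks[lab])
            assigned: dict[int, int] = {}
            if dets:
                cost = np.full((len(order), len(dets)), _SENTINEL)
                for i, lab in enumerate(order):
                    for k, d in enumerate(dets):
                        dist = float(np.hypot(preds[lab][0] - d.centroid[0],
                                              preds[lab][1] - d.centroid[1]))
                        if dist <= params.gate:
                            cost[i, k] = dist
                pairs, _ = assign_hungarian(cost)
                for i, k in pairs:
                    if cost[i, k] < _SENTINEL:
                        assigned[order[i]] = k
            for lab in order:
                tr = tracks[lab]
                key = (cam, lab)
                if lab in assigned:
                    z = dets[assigned[lab]].centroid
                    kf_update(tr, z)
                    tr.coast = 0
                    trackset.positions[key][t] = z
                    trackset.status[key][t] = MEASURED
                else:
                    tr.coast += 1
                    trackset.positions[key][t] = preds[lab]
                    trackset.status[key][t] = (
                        LOST if tr.coast > params.max_coast else PREDICTED
                    )


def track_markers(
    detections: DetectionSet,
    labeling: InitialLabeling,
    gate: float = 30.0,
    q: float = 1.0,
    r: float = 1.0,
    max_coast: int = 15,
) -> TrackSet:
    """Maintain marker identities through time from an initial labeling.

    Tracking runs forward from ``t0`` and, when ``t0 > 0``, independently
    backward over earlier frames with time-reversed dynamics.  At every
    timestep the assignment cost is the Euclidean distance between Kalman
    predictions and detection centroids; pairs farther than ``gate`` are
    forbidden.  Unassigned tracks coast on their prediction and are marked
    lost after ``max_coast`` consecutive coasting frames (they keep
    competing for detections inside the gate and recover on re-capture).
    """
    params = TrackingParams(gate=gate, q=q, r=r, max_coast=max_coast)
    labeling.validate(min_cameras=1)
    t0 = labeling.t0
    T = detections.n_timesteps
    if not (0 <= t0 < T):
        raise ValueError(f"t0={t0} outside the detection range [0, {T})")
    any_visible = False
    for cam, m in labeling.assignments.items():
        dets0 = detections.get(t0, cam)
        for lab, idx in m.items():
            if not (0 <= idx < len(dets0)):
                raise ValueError(
                    f"label {lab}: detection index {idx} does not exist in "
                    f"camera {cam} at t0={t0}"
                )
            any_visible = True
    if not any_visible:
        raise ValueError("no label is visible in any camera at t0")

    cams = sorted(labeling.assignments)
    ts = TrackSet(T, cams, labeling.labels())
    _track_direction(detections, labeling, params, range(t0 + 1, T), ts)
    if t0 > 0:
        _track_direction(detections, labeling, params, range(t0 - 1, -1, -1), ts)
    return ts


def snap_labeling(
    detections: DetectionSet,
    t0: int,
    clicks: Mapping[int, Mapping[int, tuple[float, float]]],
) -> InitialLabeling:
    """Snap user clicks (camera → label → approximate (u, v)) to the
    nearest detection at ``t0`` — clicks need not be pixel precise."""
    assignments: dict[int, dict[int, int]] = {}
    for cam, lab_map in clicks.items():
        dets = detections.get(t0, cam)
        if not dets:
            continue
        cents = np.array([d.centroid for d in dets])
        taken: set[int] = set()
        assignments[cam] = {}
        for lab, (u, v) in sorted(lab_map.items()):
            d2 = np.sum((cents - (u, v)) ** 2, axis=1)
            for idx in np.argsort(d2):
                if int(idx) not in taken:
                    taken.add(int(idx))
                    assignments[cam][lab] = int(idx)
                    break
    return InitialLabeling(t0=t0, assignments=assignments)


# ---------------------------------------------------------------------------
# correspondence plugin contract
# ---------------------------------------------------------------------------

class PluginValidationError(ValueError):
    pass


# a correspondence engine consumes detections + labeling and returns a TrackSet
CorrespondenceFn = Callable[..., TrackSet]

_REGISTRY: dict[str, CorrespondenceFn] = {}


def register_correspondence(name: str, fn: CorrespondenceFn) -> None:
    """Register a correspondence engine under a resolvable name.

    The engine must honor the built-in signature
    ``fn(detections, labeling, **params) -> TrackSet``.
    """
    _REGISTRY[name] = fn


def get_correspondence(name: str) -> CorrespondenceFn:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"no correspondence engine named {name!r}; "
            f"registered: {sorted(_REGISTRY)}"
        ) from None


def validate_correspondence_output(trackset: TrackSet) -> None:
    """Check the plugin contract: per camera and timestep, labels unique.

    The TrackSet container keys by (camera, label) so duplicate labels can
    only arise from a plugin emitting two tracks claiming the same
    detection slot; we check that measured positions are distinct per
    camera/timestep and that every status code is recognized.
    """
    valid_status = {MEASURED, PREDICTED, LOST, ABSENT}
    for t in range(trackset.n_timesteps):
        for cam in trackset.cameras:
            seen: dict[tuple[float, float], int] = {}
            for lab in trackset.labels:
                st = trackset.status[(cam, lab)][t]
                if st not in valid_status:
                    raise PluginValidationError(
                        f"t={t} camera={cam} label={lab}: unknown status {st!r}"
                    )
                if st == MEASURED:
                    u, v = trackset.positions[(cam, lab)][t]
                    key = (round(float(u), 9), round(float(v), 9))
                    if key in seen:
                        raise PluginValidationError(
                            f"duplicate label assignment at t={t} camera={cam}: "
                            f"labels {seen[key]} and {lab} share a detection"
                        )
                    seen[key] = lab


register_correspondence("kalman_hungarian", track_markers)
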