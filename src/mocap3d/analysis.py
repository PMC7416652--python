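"""Accuracy and kinematics evaluation of triangulated trajectories.

Covers the evaluation toolbox of the system: interpoint-distance error
against a known reference geometry, total-least-squares plane fitting,
stationary deviation, forward–backward (RTS) trajectory smoothing, and
strike kinematics — per-step velocity profiles, velocity-threshold
masking of identity-swap artifacts, per-strike metrics and group
aggregates.  Trajectories are in mm internally; kinematics are reported
in m, s and m/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .triangulation import Trajectory3D

__all__ = [
    "PlaneFit",
    "StrikeMetrics",
    "interpoint_errors",
    "fit_plane",
    "stationary_deviation",
    "smooth_trajectory",
    "velocity_profile",
    "mask_by_velocity",
    "strike_metrics",
    "aggregate_trials",
    "fit_velocity_curve",
    "capacity_estimate",
]


@dataclass(frozen=True)
class PlaneFit:
    """Least-error plane through a point set (total least squares)."""

    normal: np.ndarray  # unit 3-vector
    centroid: np.ndarray  # mm
    rms_distance: float  # mm
    per_point_distance: np.ndarray  # mm


@dataclass(frozen=True)
class StrikeMetrics:
    """Kinematics of one strike window.

    ``mean_speed = path_distance / duration``; ``max_velocity`` is the
    largest per-step speed among unmasked steps (not guaranteed to exceed
    the mean when steps were masked out).
    """

    duration: float  # s
    path_distance: float  # m
    mean_speed: float  # m/s
    max_velocity: float  # m/s
    masked_steps: tuple[int, ...] = ()


def interpoint_errors(
    traj: Trajectory3D,
    reference: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signed interpoint-distance errors against a reference geometry.

    ``reference`` is the M×M matrix of true pairwise marker distances
    (mm).  For each frame where both markers of an unordered pair (i, j)
    are valid, the error is ``‖p_i − p_j‖ − d_ij``.  Returns the per-frame
    error table and a per-pair summary (mean, median, IQR), the summary
    mirroring boxplot panels of interpoint error per pair.
    """
    ref = np.asarray(reference, dtype=float)
    M = traj.n_markers
    if ref.shape != (M, M):
        raise ValueError(f"reference must be {M}x{M}")
    if np.max(np.abs(ref - ref.T)) > 1e-9:
        raise ValueError("reference distance matrix must be symmetric")
    if np.max(np.abs(np.diag(ref))) > 1e-9:
        raise ValueError("reference distance matrix must have zero diagonal")
    rows = []
    for i, j in combinations(range(M), 2):
        both = traj.valid[:, i] & traj.valid[:, j]
        d = np.linalg.norm(traj.positions[:, i, :] - traj.positions[:, j, :],
                           axis=1)
        err = d - ref[i, j]
        for t in np.nonzero(both)[0]:
            rows.append({"t": int(t), "pair": f"{traj.labels[i]}-{traj.labels[j]}",
                         "error_mm": err[t]})
    errors = pd.DataFrame(rows, columns=["t", "pair", "error_mm"])
    if len(errors):
        g = errors.groupby("pair")["error_mm"]
        summary = pd.DataFrame({
            "mean": g.mean(),
            "median": g.median(),
            "iqr": g.quantile(0.75) - g.quantile(0.25),
            "mean_abs": g.apply(lambda s: s.abs().mean()),
        }).reset_index()
    else:
        summary = pd.DataFrame(columns=["pair", "mean", "median", "iqr",
                                        "mean_abs"])
    return errors, summary


def fit_plane(points: np.ndarray) -> PlaneFit:
    """Total-least-squares plane via SVD of the centered coordinates.

    The normal is the singular vector of smallest singular value; the
    fitted plane passes through the centroid.  Point distances are
    absolute point-plane distances.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise ValueError("plane fitting needs at least 3 points")
    c = pts.mean(axis=0)
    centered = pts - c
    _, s, Vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate input: points are collinear or coincident")
    normal = Vt[-1]
    dist = np.abs(centered @ normal)
    return PlaneFit(normal=normal, centroid=c,
                    rms_distance=float(np.sqrt(np.mean(dist ** 2))),
                    per_point_distance=dist)


def stationary_deviation(traj: Trajectory3D) -> dict[int, np.ndarray]:
    """Per-marker Euclidean distance from the temporal mean position.

    Quantifies how much a physically stationary marker wanders in the
    reconstruction.  Requires every frame valid for each marker reported.
    """
    out = {}
    for m, lab in enumerate(traj.labels):
        if not np.any(traj.valid[:, m]):
            raise ValueError(f"marker {lab}: no valid frames")
        if not np.all(traj.valid[:, m]):
            raise ValueError(
                f"marker {lab}: stationary deviation needs all frames valid"
            )
        p = traj.positions[:, m, :]
        out[lab] = np.linalg.norm(p - p.mean(axis=0), axis=1)
    return out


# ---------------------------------------------------------------------------
# forward-backward smoothing
# ---------------------------------------------------------------------------

def _rts_smooth_1d(z: np.ndarray, valid: np.ndarray, q: float, r: float
                   ) -> np.ndarray:
    """Constant-velocity Kalman filter + RTS smoother on one coordinate.

    Invalid frames are bridged by prediction (no measurement update).
    """
    T = len(z)
    F = np.array([[1.0, 1.0], [0.0, 1.0]])
    Q = q * np.array([[0.25, 0.5], [0.5, 1.0]])
    H = np.array([[1.0, 0.0]])
    # two-point differencing start: exact on model-consistent signals
    vidx = np.nonzero(valid)[0]
    first = int(vidx[0])
    v0 = (z[vidx[1]] - z[first]) / (vidx[1] - first) if len(vidx) > 1 else 0.0
    x = np.array([z[first], v0])
    P = np.diag([r, 100.0 * r])
    xs_f = np.zeros((T, 2))
    Ps_f = np.zeros((T, 2, 2))
    xs_p = np.zeros((T, 2))
    Ps_p = np.zeros((T, 2, 2))
    for t in range(T):
        if t == 0:
            xp, Pp = x, P
        else:
            xp = F @ xs_f[t - 1]
            Pp = F @ Ps_f[t - 1] @ F.T + Q
        xs_p[t], Ps_p[t] = xp, Pp
        if valid[t]:
            S = float((H @ Pp @ H.T).item()) + r
            K = (Pp @ H.T / S).ravel()
            xf = xp + K * (z[t] - xp[0])
            Pf = Pp - np.outer(K, H @ Pp)
        else:
            xf, Pf = xp, Pp
        xs_f[t], Ps_f[t] = xf, 0.5 * (Pf + Pf.T)
    xs = xs_f.copy()
    Ps = Ps_f.copy()
    for t in range(T - 2, -1, -1):
        C = Ps_f[t] @ F.T @ np.linalg.inv(Ps_p[t + 1])
        xs[t] = xs_f[t] + C @ (xs[t + 1] - xs_p[t + 1])
        Ps[t] = Ps_f[t] + C @ (Ps[t + 1] - Ps_p[t + 1]) @ C.T
    return xs[:, 0]


def smooth_trajectory(traj: Trajectory3D, q: float = 0.01, r: float = 1.0
                      ) -> Trajectory3D:
    """Forward–backward filter of the 3D trajectory.

    A constant-velocity Kalman filter is run forward and combined with a
    backward pass (Rauch–Tung–Striebel smoothing), independently per
    marker and axis.  ``q`` is the process-noise intensity in mm²/frame³
    (how much acceleration the motion model tolerates) and ``r`` the
    measurement noise in mm².  Invalid frames are bridged by prediction
    but stay flagged invalid in the output.
    """
    pos = traj.positions.copy()
    for m in range(traj.n_markers):
        v = traj.valid[:, m]
        if not np.any(v):
            continue
        for ax in range(3):
            z = np.where(v, traj.positions[:, m, ax], 0.0)
            pos[:, m, ax] = _rts_smooth_1d(z, v, q, r)
    return Trajectory3D(pos, traj.valid.copy(), traj.frame_rate_hz,
                        list(traj.labels), traj.n_cameras.copy(),
                        traj.reproj_rms.copy())


# ---------------------------------------------------------------------------
# strike kinematics
# ---------------------------------------------------------------------------

def velocity_profile(traj: Trajectory3D, label: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-step speed series in m/s with a step-validity mask.

    ``v[t] = ‖p_t − p_{t−1}‖ · frame_rate`` (mm → m), the change in
    distance between two subsequent timesteps; ``v[0]`` is undefined, as
    is any step with an invalid endpoint.  Returns ``(speeds, step_valid)``
    arrays of length T.
    """
    if label not in traj.labels:
        raise KeyError(f"unknown marker label {label!r}")
    p, valid = traj.marker(label)
    T = traj.n_timesteps
    speeds = np.full(T, np.nan)
    step_valid = np.zeros(T, dtype=bool)
    d = np.linalg.norm(np.diff(p, axis=0), axis=1)  # mm per frame
    ok = valid[1:] & valid[:-1]
    speeds[1:][ok] = d[ok] * traj.frame_rate_hz / 1000.0
    step_valid[1:] = ok
    return speeds, step_valid


def mask_by_velocity(speeds: np.ndarray,
                     step_valid: np.ndarray | None = None,
                     threshold: float = 2.5) -> np.ndarray:
    """Sample-validity mask from a per-step speed series.

    Steps with speed above ``threshold`` (m/s) are physically implausible
    — typically identity swaps or spurious thresholding hits — and both
    endpoint samples of each offending step become suspect.  A sample is
    dropped only when *all* of its (valid) incident steps offend.  Returns
    a boolean keep-mask over samples.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    v = np.asarray(speeds, dtype=float)
    T = len(v)
    if step_valid is None:
        step_valid = np.isfinite(v)
        step_valid[0] = False
    offend = step_valid & (v > threshold)
    keep = np.ones(T, dtype=bool)
    for t in range(T):
        incident = []
        if t >= 1 and step_valid[t]:
            incident.append(offend[t])
        if t + 1 < T and step_valid[t + 1]:
            incident.append(offend[t + 1])
        if incident and all(incident):
            keep[t] = False
    return keep


def strike_metrics(
    traj: Trajectory3D,
    label: int,
    window: tuple[int, int],
    threshold: float = 2.5,
) -> StrikeMetrics:
    """Kinematics over an explicit strike window ``(t_start, t_end)``.

    The window — from initial forward movement to the start of head
    retraction — is a user decision, not auto-detected.  Velocity-threshold
    masking is applied first; over the remaining valid steps inside the
    window: ``path_distance = Σ‖Δp‖`` (m), ``duration`` is the window span
    in s, ``mean_speed = path_distance/duration`` and ``max_velocity`` the
    largest per-step speed.
    """
    t_start, t_end = window
    if not (0 <= t_start < t_end < traj.n_timesteps):
        raise ValueError(
            f"window {window} invalid for trajectory of length "
            f"{traj.n_timesteps} (need t_start < t_end)"
        )
    speeds, step_valid = velocity_profile(traj, label)
    keep = mask_by_velocity(speeds, step_valid, threshold)
    m = traj.labels.index(label)
    p = traj.positions[:, m, :]
    use_sample = traj.valid[:, m] & keep
    steps = []
    masked = []
    for t in range(t_start + 1, t_end + 1):
        if step_valid[t] and use_sample[t] and use_sample[t - 1]:
            steps.append(t)
        elif step_valid[t]:
            masked.append(t)
    if not steps:
        raise ValueError("no valid unmasked steps in the strike window")
    path_mm = sum(float(np.linalg.norm(p[t] - p[t - 1])) for t in steps)
    duration = (t_end - t_start) / traj.frame_rate_hz
    path_m = path_mm / 1000.0
    return StrikeMetrics(
        duration=duration,
        path_distance=path_m,
        mean_speed=path_m / duration,
        max_velocity=float(np.nanmax(speeds[steps])),
        masked_steps=tuple(masked),
    )


def aggregate_trials(
    trials: Sequence[StrikeMetrics] | pd.DataFrame,
    grouping: Sequence | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Arithmetic means of strike metrics per group and overall.

    ``trials`` is a sequence of :class:`StrikeMetrics` (with ``grouping``
    giving e.g. the subject of each trial) or a DataFrame with columns
    ``duration_s, distance_m, speed_ms, max_velocity_ms`` (+ optional
    ``subject``).  Returns ``(per_group_means, overall_means)``.
    """
    if isinstance(trials, pd.DataFrame):
        df = trials.copy()
        if grouping is not None:
            df["subject"] = list(grouping)
    else:
        if len(trials) == 0:
            raise ValueError("need at least one trial")
        df = pd.DataFrame({
            "duration_s": [t.duration for t in trials],
            "distance_m": [t.path_distance for t in trials],
            "speed_ms": [t.mean_speed for t in trials],
            "max_velocity_ms": [t.max_velocity for t in trials],
        })
        df["subject"] = list(grouping) if grouping is not None else "all"
    cols = ["duration_s", "distance_m", "speed_ms", "max_velocity_ms"]
    if "subject" in df.columns:
        per_group = df.groupby("subject")[cols].mean().reset_index()
    else:
        per_group = pd.DataFrame(columns=["subject"] + cols)
    overall = df[cols].mean()
    return per_group, overall


def fit_velocity_curve(
    speeds: np.ndarray | Sequence[np.ndarray],
    degree: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares polynomial fit of a velocity-vs-time profile.

    Accepts one speed series (NaN = invalid) or several, which are pooled
    after aligning each to its window start — the "average best fit" for a
    group of trials.  Returns ``(coefficients, fitted_series)`` where the
    fitted series is evaluated on the longest trial's time base.
    """
    if isinstance(speeds, np.ndarray) and speeds.ndim == 1:
        series = [speeds]
    else:
        series = [np.asarray(s, dtype=float) for s in speeds]
    ts, vs = [], []
    for s in series:
        t = np.arange(len(s), dtype=float)
        ok = np.isfinite(s)
        ts.append(t[ok])
        vs.append(s[ok])
    t_all = np.concatenate(ts)
    v_all = np.concatenate(vs)
    if len(t_all) < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} valid samples for degree {degree}"
        )
    coeffs = np.polyfit(t_all, v_all, degree)
    t_eval = np.arange(max(len(s) for s in series), dtype=float)
    return coeffs, np.polyval(coeffs, t_eval)


def capacity_estimate(
    n_cameras: int,
    width: int,
    height: int,
    bytes_per_pixel: int,
    frame_rate_hz: float,
    seconds: float,
) -> int:
    """Raw capture-buffer size in bytes (no container or overhead).

    The product of camera count, frame area, pixel depth, frame rate and
    recording time — the minimum RAM needed to hold a capture.
    """
    for name, val in [("n_cameras", n_cameras), ("width", width),
                      ("height", height), ("bytes_per_pixel", bytes_per_pixel),
                      ("frame_rate_hz", frame_rate_hz), ("seconds", seconds)]:
        if val < 0:
            raise ValueError(f"{name} must be non-negative")
    return int(n_cameras * width * height * bytes_per_pixel
               * frame_rate_hz * seconds)
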