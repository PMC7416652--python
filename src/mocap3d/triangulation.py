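"""Multi-view triangulation: DLT/SVD solve plus reprojection-optimal correction.

Observed pixels are undistorted, then a 3D point is found for every marker
and timestep.  The algebraic DLT solution seeds an iterative correction
that translocates each observed pixel a minimal amount so all camera rays
intersect — equivalently, it returns the 3D point minimizing the summed
squared reprojection error.  A camera-subset fallback handles occlusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .camera import CameraRig, project, undistort_pixel
from .tracking import TrackSet

__all__ = [
    "CorrectedObservation",
    "TriangulatedPoint",
    "Trajectory3D",
    "triangulate_dlt",
    "triangulate_optimal",
    "triangulate_sequence",
    "export_ply",
]


class DegenerateGeometryError(ValueError):
    """Rays parallel / rank-deficient / point at infinity."""


@dataclass(frozen=True)
class CorrectedObservation:
    camera: int
    original: np.ndarray  # undistorted observation (u, v)
    corrected: np.ndarray  # reprojection of the returned 3D point

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.corrected - self.original))


@dataclass(frozen=True)
class TriangulatedPoint:
    position: np.ndarray  # (3,) mm
    cameras_used: tuple[int, ...]
    reprojection_rms: float
    iterations: int
    converged: bool


@dataclass
class Trajectory3D:
    """T×M 3D marker paths with validity mask and residual bookkeeping."""

    positions: np.ndarray  # (T, M, 3) mm, NaN where invalid
    valid: np.ndarray  # (T, M) bool
    frame_rate_hz: float
    labels: list[int]
    n_cameras: np.ndarray | None = None  # (T, M) int
    reproj_rms: np.ndarray | None = None  # (T, M) px

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        T, M = self.valid.shape
        if self.positions.shape != (T, M, 3):
            raise ValueError("positions/valid shape mismatch")
        if self.n_cameras is None:
            self.n_cameras = np.zeros((T, M), dtype=int)
        if self.reproj_rms is None:
            self.reproj_rms = np.full((T, M), np.nan)

    @property
    def n_timesteps(self) -> int:
        return self.valid.shape[0]

    @property
    def n_markers(self) -> int:
        return self.valid.shape[1]

    def marker(self, label: int) -> tuple[np.ndarray, np.ndarray]:
        """(positions (T,3), valid (T,)) for one marker label."""
        m = self.labels.index(label)
        return self.positions[:, m, :], self.valid[:, m]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in range(self.n_timesteps):
            for m, lab in enumerate(self.labels):
                x, y, z = self.positions[t, m]
                rows.append({
                    "t": t, "label": lab, "x_mm": x, "y_mm": y, "z_mm": z,
                    "valid": bool(self.valid[t, m]),
                    "n_cameras": int(self.n_cameras[t, m]),
                    "reproj_rms": self.reproj_rms[t, m],
                })
        return pd.DataFrame(rows, columns=["t", "label", "x_mm", "y_mm",
                                           "z_mm", "valid", "n_cameras",
                                           "reproj_rms"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       frame_rate_hz: float) -> "Trajectory3D":
        labels = sorted(df["label"].unique().tolist())
        T = int(df["t"].max()) + 1
        M = len(labels)
        pos = np.full((T, M, 3), np.nan)
        valid = np.zeros((T, M), dtype=bool)
        ncam = np.zeros((T, M), dtype=int)
        rms = np.full((T, M), np.nan)
        lut = {lab: i for i, lab in enumerate(labels)}
        for _, r in df.iterrows():
            t, m = int(r["t"]), lut[r["label"]]
            pos[t, m] = (r["x_mm"], r["y_mm"], r["z_mm"])
            valid[t, m] = bool(r["valid"])
            ncam[t, m] = int(r["n_cameras"])
            rms[t, m] = r["reproj_rms"]
        return cls(pos, valid, frame_rate_hz, labels, ncam, rms)

    @classmethod
    def from_csv(cls, path, frame_rate_hz: float) -> "Trajectory3D":
        return cls.from_dataframe(pd.read_csv(path, float_precision="round_trip"), frame_rate_hz)


# ---------------------------------------------------------------------------
# core solvers (inputs are *undistorted* pixels)
# ---------------------------------------------------------------------------


def _as_obs_items(observations) -> list[tuple[int, np.ndarray]]:
    """Accept camera→pixel mappings or (camera, pixel) pair sequences."""
    if isinstance(observations, Mapping):
        items = list(observations.items())
    else:
        items = [(int(c), uv) for c, uv in observations]
    return [(c, np.asarray(uv, dtype=float)) for c, uv in items]


def _normalized_rays(items, rig: CameraRig) -> list[tuple[int, np.ndarray]]:
    """Pixel → normalized image coordinates, keeping camera indices."""
    out = []
    for cam_idx, uv in items:
        K = rig[cam_idx].intrinsics
        out.append((cam_idx,
                    np.array([(uv[0] - K.cx) / K.fx, (uv[1] - K.cy) / K.fy])))
    return out


def triangulate_dlt(observations, rig: CameraRig) -> np.ndarray:
    """Algebraic triangulation by SVD of the homogeneous DLT system.

    ``observations`` maps camera index → undistorted pixel (u, v) (or is a
    sequence of ``(camera, pixel)`` pairs); at least two observations are
    required.  Exact on noiseless observations.
    """
    items = _as_obs_items(observations)
    if len(items) < 2:
        raise DegenerateGeometryError(
            f"triangulation needs >= 2 observations, got {len(items)}"
        )
    xn = _normalized_rays(items, rig)
    rows = []
    for cam_idx, (x, y) in xn:
        P = rig[cam_idx].projection_matrix_normalized()
        rows.append(x * P[2] - P[0])
        rows.append(y * P[2] - P[1])
    A = np.asarray(rows)
    _, s, Vt = np.linalg.svd(A)
    X = Vt[-1]
    if abs(X[3]) < 1e-12:
        raise DegenerateGeometryError(
            "point at infinity: parallel rays or rank-deficient geometry"
        )
    # a well-posed 2+ camera system has rank 3; rank < 3 means the camera
    # rows are linearly dependent (e.g. the same camera twice)
    if s[2] < 1e-9 * s[0]:
        raise DegenerateGeometryError(
            "rank-deficient DLT system: observations do not constrain a "
            "unique 3D point (parallel or duplicated rays)"
        )
    return X[:3] / X[3]


def _reprojection_residuals(point: np.ndarray, items,
                            rig: CameraRig) -> np.ndarray:
    res = []
    for cam_idx, uv in items:
        proj = project(point, rig[cam_idx], apply_distortion=False)
        res.extend(proj - uv)
    return np.asarray(res)


def _reprojection_jacobian(point: np.ndarray, items,
                           rig: CameraRig) -> np.ndarray:
    rows = []
    for cam_idx, _uv in items:
        cam = rig[cam_idx]
        R = cam.pose.rotation
        pc = cam.pose.transform(point)
        x, y, z = pc
        K = cam.intrinsics
        # d(u,v)/d(pc) for the undistorted pinhole
        J_pc = np.array([[K.fx / z, 0.0, -K.fx * x / z**2],
                         [0.0, K.fy / z, -K.fy * y / z**2]])
        rows.append(J_pc @ R)
    return np.vstack(rows)


def triangulate_optimal(
    observations,
    rig: CameraRig,
    tol: float = 1e-10,
    max_iter: int = 20,
) -> tuple[TriangulatedPoint, list[CorrectedObservation]]:
    """Reprojection-error-optimal triangulation by iterative correction.

    Starting from the DLT solution, each iteration translocates the
    observed pixels toward consistency by a damped Gauss–Newton step on the
    3D point; it terminates when the change in the total squared correction
    falls below ``tol`` (px²) or after ``max_iter`` iterations (flagged,
    best iterate returned — noisy batch sequences must not die mid-run).
    The corrected pixels are the reprojections of the returned point, so
    their rays intersect at it by construction.  Typically converges in a
    couple of iterations.
    """
    items = _as_obs_items(observations)
    X = triangulate_dlt(items, rig)
    res = _reprojection_residuals(X, items, rig)
    cost = float(res @ res)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        J = _reprojection_jacobian(X, items, rig)
        try:
            step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        except np.linalg.LinAlgError:
            break
        # damped: never accept a cost increase (monotone total correction)
        lam = 1.0
        new_cost = cost
        for _ in range(20):
            X_try = X + lam * step
            try:
                res_try = _reprojection_residuals(X_try, items, rig)
            except ValueError:
                lam *= 0.5
                continue
            new_cost = float(res_try @ res_try)
            if new_cost <= cost:
                X, res = X_try, res_try
                break
            lam *= 0.5
        if abs(cost - new_cost) < tol:
            cost = new_cost
            converged = True
            break
        cost = new_cost

    corrected = []
    for cam_idx, uv in items:
        reproj = project(X, rig[cam_idx], apply_distortion=False)
        corrected.append(CorrectedObservation(cam_idx, uv, reproj))
    rms = float(np.sqrt(np.mean([c.magnitude ** 2 for c in corrected])))
    pt = TriangulatedPoint(
        position=X,
        cameras_used=tuple(sorted(c for c, _ in items)),
        reprojection_rms=rms,
        iterations=it,
        converged=converged or rms == 0.0,
    )
    return pt, corrected


def triangulate_sequence(
    tracks: TrackSet,
    rig: CameraRig,
    min_cameras: int = 2,
    require_all: bool = False,
    tol: float = 1e-10,
    max_iter: int = 20,
) -> Trajectory3D:
    """Triangulate every (timestep, label) from measured track positions.

    Per timestep and label, the cameras whose track status is ``measured``
    are gathered; with ``require_all`` any missing camera invalidates the
    point (skip semantics), otherwise the method falls back to the subset
    of unoccluded cameras as long as at least ``min_cameras`` remain.
    Pixels are undistorted before solving.  Invalidity is recorded in the
    mask, never raised.
    """
    T = tracks.n_timesteps
    labels = list(tracks.labels)
    M = len(labels)
    n_rig = len(rig)
    pos = np.full((T, M, 3), np.nan)
    valid = np.zeros((T, M), dtype=bool)
    ncam = np.zeros((T, M), dtype=int)
    rms = np.full((T, M), np.nan)
    for t in range(T):
        for m, lab in enumerate(labels):
            obs = tracks.measured_at(t, lab)
            if require_all and len(obs) < n_rig:
                continue
            if len(obs) < max(2, min_cameras):
                continue
            und = {c: undistort_pixel(uv, rig[c]) for c, uv in obs.items()}
            try:
                pt, _ = triangulate_optimal(und, rig, tol=tol,
                                            max_iter=max_iter)
            except DegenerateGeometryError:
                continue
            pos[t, m] = pt.position
            valid[t, m] = True
            ncam[t, m] = len(pt.cameras_used)
            rms[t, m] = pt.reprojection_rms
    return Trajectory3D(pos, valid, rig.frame_rate_hz, labels, ncam, rms)


# ---------------------------------------------------------------------------
# PLY export
# ---------------------------------------------------------------------------


def export_ply(traj: Trajectory3D, path, *, timestamped: bool = True) -> None:
    """Write the trajectory as an ASCII PLY point cloud for external viewers.

    With ``timestamped=True`` a single cloud is written with per-vertex
    frame index and label properties; otherwise only marker positions.
    """
    pts = []
    for t in range(traj.n_timesteps):
        for m, lab in enumerate(traj.labels):
            if traj.valid[t, m]:
                x, y, z = traj.positions[t, m]
                pts.append((x, y, z, t, lab))
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(pts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        if timestamped:
            fh.write("property int frame\nproperty int label\n")
        fh.write("end_header\n")
        for x, y, z, t, lab in pts:
            if timestamped:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f} {t} {lab}\n")
            else:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
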