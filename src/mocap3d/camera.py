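"""Pinhole camera model with Brown–Conrady distortion, rigs, and resectioning.

Conventions
-----------
* Pixel coordinates are continuous, origin at the top-left pixel *center*,
  ``u`` (x) to the right and ``v`` (y) down; integer coordinates address
  pixel centers.
* World units are millimeters.  Camera 0 of a rig anchors the world frame:
  its pose is exactly the identity.
* The distortion model is the 5-coefficient Brown–Conrady polynomial
  (k1, k2, k3 radial; p1, p2 tangential), applied on normalized image
  coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "DistortionCoeffs",
    "CameraPose",
    "Camera",
    "CameraRig",
    "BehindCameraError",
    "CalibrationError",
    "project",
    "undistort_pixel",
    "reprojection_rms",
    "resect_camera",
    "load_rig",
    "save_rig",
]


class BehindCameraError(ValueError):
    """A world point has non-positive depth in a camera frame."""

    def __init__(self, camera_index: int | None, depth: float):
        self.camera_index = camera_index
        self.depth = depth
        super().__init__(
            f"point behind camera (index={camera_index}, z_cam={depth:.6g} mm)"
        )


class CalibrationError(ValueError):
    """A calibration file or rig violates a structural invariant."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Focal lengths, principal point, and sensor size, all in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float
    image_width: int
    image_height: int

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise CalibrationError("focal lengths must be positive")
        if not (0 <= self.cx < self.image_width):
            raise CalibrationError("cx outside [0, image_width)")
        if not (0 <= self.cy < self.image_height):
            raise CalibrationError("cy outside [0, image_height)")


@dataclass(frozen=True)
class DistortionCoeffs:
    """Brown–Conrady coefficients; all-zero means an ideal pinhole."""

    k1: float = 0.0
    k2: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    k3: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.k1, self.k2, self.p1, self.p2, self.k3)
        if not all(np.isfinite(v) for v in vals):
            raise CalibrationError("distortion coefficients must be finite")

    @property
    def is_zero(self) -> bool:
        return self.k1 == self.k2 == self.k3 == self.p1 == self.p2 == 0.0

    def as_array(self) -> np.ndarray:
        # OpenCV-style ordering (k1, k2, p1, p2, k3)
        return np.array([self.k1, self.k2, self.p1, self.p2, self.k3])


_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class CameraPose:
    """World→camera rigid transform: ``x_cam = R @ x_world + t`` (t in mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-6:
            raise CalibrationError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise CalibrationError("rotation has negative determinant (reflection)")

    @classmethod
    def identity(cls) -> "CameraPose":
        return cls(np.eye(3), np.zeros(3))

    @property
    def is_identity(self) -> bool:
        return (
            np.max(np.abs(self.rotation - np.eye(3))) <= _ORTHO_TOL
            and np.max(np.abs(self.translation)) <= _ORTHO_TOL
        )

    def transform(self, points_world: np.ndarray) -> np.ndarray:
        pts = np.asarray(points_world, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "CameraPose":
        return CameraPose(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "CameraPose") -> "CameraPose":
        """Pose of ``self ∘ other``: apply ``other`` first, then ``self``."""
        return CameraPose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass(frozen=True)
class Camera:
    """One rig entry: intrinsics, distortion, and pose in the world frame."""

    intrinsics: CameraIntrinsics
    distortion: DistortionCoeffs = field(default_factory=DistortionCoeffs)
    pose: CameraPose = field(default_factory=CameraPose.identity)
    index: int | None = None

    @property
    def center_world(self) -> np.ndarray:
        """Optical center in world coordinates."""
        return -self.pose.rotation.T @ self.pose.translation

    def projection_matrix_normalized(self) -> np.ndarray:
        """3×4 matrix ``[R | t]`` mapping world mm to normalized image coords."""
        return np.hstack([self.pose.rotation, self.pose.translation[:, None]])


@dataclass
class CameraRig:
    """Ordered collection of cameras; camera 0 defines the world frame."""

    cameras: list[Camera]
    frame_rate_hz: float = 750.0

    def __post_init__(self) -> None:
        if len(self.cameras) < 2:
            raise CalibrationError("a rig needs at least 2 cameras for triangulation")
        if self.frame_rate_hz <= 0:
            raise CalibrationError("frame_rate_hz must be positive")
        self.cameras = [
            Camera(c.intrinsics, c.distortion, c.pose, index=i)
            for i, c in enumerate(self.cameras)
        ]
        if not self.cameras[0].pose.is_identity:
            raise CalibrationError(
                "camera 0 must carry the identity pose (world-frame anchor)"
            )

    def __len__(self) -> int:
        return len(self.cameras)

    def __getitem__(self, i: int) -> Camera:
        return self.cameras[i]

    def __iter__(self):
        return iter(self.cameras)


# ---------------------------------------------------------------------------
# projection / undistortion
# ---------------------------------------------------------------------------


def _distort_normalized(xy: np.ndarray, dist: DistortionCoeffs) -> np.ndarray:
    x = xy[..., 0]
    y = xy[..., 1]
    r2 = x * x + y * y
    radial = 1.0 + r2 * (dist.k1 + r2 * (dist.k2 + r2 * dist.k3))
    xd = x * radial + 2.0 * dist.p1 * x * y + dist.p2 * (r2 + 2.0 * x * x)
    yd = y * radial + dist.p1 * (r2 + 2.0 * y * y) + 2.0 * dist.p2 * x * y
    return np.stack([xd, yd], axis=-1)


def project(
    point_world: np.ndarray,
    camera: Camera,
    *,
    apply_distortion: bool = True,
) -> np.ndarray:
    """Project world point(s) (mm) to pixel coordinates ``(u, v)``.

    Raises :class:`BehindCameraError` if any point has non-positive depth.
    Accepts a single 3-vector or an ``(..., 3)`` array.
    """
    pts = np.asarray(point_world, dtype=float)
    single = pts.ndim == 1
    cam_pts = camera.pose.transform(np.atleast_2d(pts))
    z = cam_pts[..., 2]
    if np.any(z <= 0):
        raise BehindCameraError(camera.index, float(np.min(z)))
    xy = cam_pts[..., :2] / z[..., None]
    if apply_distortion and not camera.distortion.is_zero:
        xy = _distort_normalized(xy, camera.distortion)
    K = camera.intrinsics
    uv = np.stack([K.fx * xy[..., 0] + K.cx, K.fy * xy[..., 1] + K.cy], axis=-1)
    return uv[0] if single else uv.reshape(pts.shape[:-1] + (2,))


@dataclass(frozen=True)
class UndistortResult:
    pixel: np.ndarray
    converged: bool
    residual: float  # normalized-coordinate residual of the fixed point
    iterations: int


def undistort_pixel(
    pixel: np.ndarray,
    camera: Camera,
    *,
    max_iter: int = 20,
    tol: float = 1e-9,
    full_output: bool = False,
):
    """Map observed pixel(s) to their ideal (distortion-free) positions.

    Inverts the Brown–Conrady map by damped fixed-point iteration on
    normalized coordinates.  With ``full_output=True`` returns an
    :class:`UndistortResult` carrying convergence status and residual.
    """
    px = np.asarray(pixel, dtype=float)
    if not np.all(np.isfinite(px)):
        raise ValueError("pixel coordinates must be finite")
    single = px.ndim == 1
    px2 = np.atleast_2d(px)
    K = camera.intrinsics
    xd = np.stack([(px2[..., 0] - K.cx) / K.fx, (px2[..., 1] - K.cy) / K.fy], axis=-1)
    dist = camera.distortion
    if dist.is_zero:
        out = px2.copy()
        res = UndistortResult(out[0] if single else out, True, 0.0, 0)
        return res if full_output else res.pixel

    xy = xd.copy()
    it = 0
    err = np.inf
    for it in range(1, max_iter + 1):
        fwd = _distort_normalized(xy, dist)
        delta = xd - fwd
        err = float(np.max(np.linalg.norm(delta, axis=-1)))
        if err < tol:
            break
        xy = xy + delta  # fixed point: x <- x + (target - distort(x))
    uv = np.stack([K.fx * xy[..., 0] + K.cx, K.fy * xy[..., 1] + K.cy], axis=-1)
    out = uv[0] if single else uv
    res = UndistortResult(out, err < tol, err, it)
    return res if full_output else res.pixel


def reprojection_rms(
    rig: CameraRig,
    points3d: Sequence[np.ndarray],
    observations: Sequence[Mapping[int, np.ndarray]],
) -> float:
    """RMS pixel distance between observations and reprojections.

    ``observations[i]`` maps camera index → observed ``(u, v)`` for point i.
    Every point must carry at least one observation.
    """
    sq = []
    if len(points3d) != len(observations):
        raise ValueError("points3d and observations length mismatch")
    for pt, obs in zip(points3d, observations):
        if len(obs) == 0:
            raise ValueError("a point with no observations contributes no residual")
        for cam_idx, uv in obs.items():
            proj = project(np.asarray(pt, float), rig[cam_idx])
            d = np.asarray(uv, float) - proj
            sq.append(float(d @ d))
    if not sq:
        raise ValueError("empty observation set")
    return float(np.sqrt(np.mean(sq)))


# ---------------------------------------------------------------------------
# resectioning (DLT pose recovery from known 3D↔2D correspondences)
# ---------------------------------------------------------------------------


def _hartley_normalize_3d(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = pts.mean(axis=0)
    d = np.linalg.norm(pts - c, axis=1).mean()
    if d < 1e-12:
        raise ValueError("degenerate 3D configuration: coincident points")
    s = np.sqrt(3.0) / d
    T = np.eye(4)
    T[:3, :3] *= s
    T[:3, 3] = -s * c
    h = np.hstack([pts, np.ones((len(pts), 1))]) @ T.T
    return h, T


def _hartley_normalize_2d(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = pts.mean(axis=0)
    d = np.linalg.norm(pts - c, axis=1).mean()
    if d < 1e-12:
        raise ValueError("degenerate 2D configuration: coincident points")
    s = np.sqrt(2.0) / d
    T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1.0]])
    h = np.hstack([pts, np.ones((len(pts), 1))]) @ T.T
    return h, T


def resect_camera(
    world_points: np.ndarray,
    pixels: np.ndarray,
    intrinsics: CameraIntrinsics,
    distortion: DistortionCoeffs | None = None,
) -> CameraPose:
    """Recover a camera pose from ≥6 (world mm, pixel) correspondences.

    Pixels are first undistorted (if coefficients are given) and mapped to
    normalized image coordinates, then the 3×4 pose matrix is solved by DLT
    with Hartley-style isotropic pre-normalization; the rotation block is
    projected to the nearest proper rotation.
    """
    X = np.asarray(world_points, dtype=float).reshape(-1, 3)
    uv = np.asarray(pixels, dtype=float).reshape(-1, 2)
    if len(X) != len(uv):
        raise ValueError("correspondence count mismatch")
    if len(X) < 6:
        raise ValueError("resectioning needs at least 6 correspondences")

    if distortion is not None and not distortion.is_zero:
        probe = Camera(intrinsics, distortion)
        uv = np.atleast_2d(undistort_pixel(uv, probe))
    xn = np.stack(
        [(uv[:, 0] - intrinsics.cx) / intrinsics.fx,
         (uv[:, 1] - intrinsics.cy) / intrinsics.fy],
        axis=-1,
    )

    Xh, T3 = _hartley_normalize_3d(X)
    xh, T2 = _hartley_normalize_2d(xn)

    n = len(X)
    A = np.zeros((2 * n, 12))
    for i in range(n):
        Xi = Xh[i]
        x, y, w = xh[i]
        A[2 * i, 4:8] = -w * Xi
        A[2 * i, 8:12] = y * Xi
        A[2 * i + 1, 0:4] = w * Xi
        A[2 * i + 1, 8:12] = -x * Xi
    _, s, Vt = np.linalg.svd(A)
    if s[-2] < 1e-12 * s[0]:
        raise ValueError(
            "degenerate configuration: resectioning system is rank deficient"
        )
    Pn = Vt[-1].reshape(3, 4)
    P = np.linalg.inv(T2) @ Pn @ T3

    # fix scale/sign so the rotation block has unit-determinant scale and
    # points sit in front of the camera
    M = P[:, :3]
    scale = np.cbrt(abs(np.linalg.det(M)))
    if scale < 1e-12:
        raise ValueError("degenerate configuration: singular rotation block")
    P = P / scale
    depths = X @ P[2, :3] + P[2, 3]
    if np.mean(depths > 0) < 0.5:
        P = -P
    U, _, Vt2 = np.linalg.svd(P[:, :3])
    R = U @ Vt2
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt2
    t = P[:, 3]
    return CameraPose(R, t)


# ---------------------------------------------------------------------------
# calibration file I/O
# ---------------------------------------------------------------------------


def _camera_to_dict(cam: Camera) -> dict:
    K = cam.intrinsics
    return {
        "fx": K.fx,
        "fy": K.fy,
        "cx": K.cx,
        "cy": K.cy,
        "width": K.image_width,
        "height": K.image_height,
        "dist": list(cam.distortion.as_array()),
        "R": [list(map(float, row)) for row in cam.pose.rotation],
        "t": list(map(float, cam.pose.translation)),
    }


def save_rig(rig: CameraRig, path) -> None:
    payload = {
        "frame_rate_hz": rig.frame_rate_hz,
        "cameras": [_camera_to_dict(c) for c in rig],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_rig(path) -> CameraRig:
    """Read a calibration JSON file, validating every structural invariant.

    Failures are collected per field and reported together in a single
    :class:`CalibrationError`.
    """
    with open(path) as fh:
        payload = json.load(fh)
    problems: list[str] = []
    if "cameras" not in payload:
        raise CalibrationError("calibration file: missing 'cameras'")
    frame_rate = payload.get("frame_rate_hz", 750.0)
    cams: list[Camera] = []
    for i, c in enumerate(payload["cameras"]):
        try:
            K = CameraIntrinsics(
                fx=float(c["fx"]), fy=float(c["fy"]),
                cx=float(c["cx"]), cy=float(c["cy"]),
                image_width=int(c["width"]), image_height=int(c["height"]),
            )
        except (KeyError, ValueError, CalibrationError) as e:
            problems.append(f"cameras[{i}].intrinsics: {e}")
            continue
        dist_vals = c.get("dist", [0, 0, 0, 0, 0])
        if len(dist_vals) != 5:
            problems.append(f"cameras[{i}].dist: expected 5 coefficients")
            continue
        k1, k2, p1, p2, k3 = map(float, dist_vals)
        try:
            D = DistortionCoeffs(k1=k1, k2=k2, p1=p1, p2=p2, k3=k3)
            pose = CameraPose(np.array(c["R"], float), np.array(c["t"], float))
        except (KeyError, ValueError, CalibrationError) as e:
            problems.append(f"cameras[{i}]: {e}")
            continue
        cams.append(Camera(K, D, pose))
    if problems:
        raise CalibrationError("; ".join(problems))
    if cams and not cams[0].pose.is_identity:
        raise CalibrationError(
            "cameras[0]: must have identity rotation and zero translation "
            "(world-frame anchor)"
        )
    return CameraRig(cams, frame_rate_hz=float(frame_rate))
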