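"""Ground-truth scene generation standing in for the capture hardware.

Builds camera rigs on an arc around a working volume, the five-marker
planar calibration board, smooth rigid board motion, strike-like
accelerating trajectories with a prescribed peak speed, rendered color
frames with light flicker, and noisy detection tables — every piece with
exact, analytically known ground truth, bit-reproducible from a seed.

Default conditions mirror the reference experimental setups: 640×480 px
sensors at 750 Hz; three cameras at ~1.1 m standoff for accuracy-board
scenes; five cameras for strike scenes; strike peak speeds and durations
in the ~1.3–2.3 m/s / 0.08–0.2 s range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .analysis import StrikeMetrics
from .camera import (Camera, CameraIntrinsics, CameraPose, CameraRig,
                     DistortionCoeffs, save_rig, project, BehindCameraError)
from .detection import Detection, DetectionSet

__all__ = [
    "SyntheticScene",
    "make_rig",
    "marker_board",
    "simulate_board_motion",
    "simulate_strike",
    "render_frame",
    "flicker_factor",
    "corrupt_detections",
    "board_scene",
    "strike_scene",
    "save_scene",
]


# ---------------------------------------------------------------------------
# rig construction
# ---------------------------------------------------------------------------


def _look_at(center: np.ndarray, target: np.ndarray) -> CameraPose:
    """World→camera pose for a camera at ``center`` aimed at ``target``."""
    z = target - center
    z = z / np.linalg.norm(z)
    up = np.array([0.0, -1.0, 0.0])  # image v grows downward
    x = np.cross(-up, z)
    if np.linalg.norm(x) < 1e-9:  # looking straight up/down
        x = np.array([1.0, 0.0, 0.0])
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])
    return CameraPose(R, -R @ center)


def make_rig(
    n_cameras: int = 3,
    standoff_mm: float = 1100.0,
    image_size: tuple[int, int] = (640, 480),
    focal_px: float = 800.0,
    distortion: DistortionCoeffs | None = None,
    arc_degrees: float = 60.0,
    frame_rate_hz: float = 750.0,
    seed: int = 0,
) -> CameraRig:
    """Cameras on a horizontal arc, all aimed at the working-volume center.

    Cameras sit at the ``standoff_mm`` radius, evenly spaced over
    ``arc_degrees``; the rig is then re-anchored so camera 0 carries the
    identity pose (world-frame convention).  The scene→world transform is
    attached as ``rig.scene_to_world`` so truth generators, which work in
    the aim-centered scene frame, can express points in the rig's world
    frame.  Construction is deterministic; ``seed`` is accepted for
    interface uniformity.
    """
    del seed  # deterministic construction
    if n_cameras < 2:
        raise ValueError("a rig needs at least 2 cameras")
    w, h = image_size
    K = CameraIntrinsics(fx=focal_px, fy=focal_px, cx=(w - 1) / 2.0,
                         cy=(h - 1) / 2.0, image_width=w, image_height=h)
    D = distortion or DistortionCoeffs()
    spacing = np.deg2rad(arc_degrees) / max(n_cameras - 1, 1)
    offsets = (np.arange(n_cameras) - (n_cameras - 1) / 2.0) * spacing
    poses = []
    target = np.zeros(3)
    for th in offsets:
        center = standoff_mm * np.array([np.sin(th), 0.0, -np.cos(th)])
        poses.append(_look_at(center, target))
    # re-anchor: world := camera-0 frame
    R0, t0 = poses[0].rotation, poses[0].translation
    cams = []
    for i, p in enumerate(poses):
        if i == 0:
            pose = CameraPose.identity()
        else:
            R = p.rotation @ R0.T
            t = p.translation - R @ t0
            pose = CameraPose(R, t)
        cams.append(Camera(K, D, pose))
    rig = CameraRig(cams, frame_rate_hz=frame_rate_hz)
    rig.scene_to_world = CameraPose(R0, t0)  # type: ignore[attr-defined]
    return rig


def _scene_to_world(rig: CameraRig, pts: np.ndarray) -> np.ndarray:
    xf: CameraPose = getattr(rig, "scene_to_world", CameraPose.identity())
    return xf.transform(pts)


# ---------------------------------------------------------------------------
# marker board and motions
# ---------------------------------------------------------------------------


def marker_board(size: str = "small") -> tuple[np.ndarray, np.ndarray]:
    """The five-marker planar accuracy board and its distance matrix (mm).

    Markers 1, 2, 4, 5 are the corners of a square (side 72 mm for the
    small board, 84 mm for the big one) and marker 3 sits at the midpoint
    of the 2–4 edge, which fixes the geometry up to isometry.  Returns
    ``(coords, distances)`` with coords centered on the board (z = 0) and
    ``distances[i, j] = ‖coords_i − coords_j‖``.
    """
    try:
        s = {"small": 72.0, "big": 84.0}[size]
    except KeyError:
        raise ValueError("size must be 'small' or 'big'") from None
    pts = np.array([
        [0.0, 0.0, 0.0],      # 1
        [s, 0.0, 0.0],        # 2
        [s, s / 2.0, 0.0],    # 3: midpoint of edge 2-4
        [s, s, 0.0],          # 4
        [0.0, s, 0.0],        # 5
    ])
    pts -= np.array([s / 2.0, s / 2.0, 0.0])
    dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return pts, dist


def simulate_board_motion(
    board: np.ndarray,
    T: int,
    speed_scale: float = 1.0,
    seed: int = 0,
    translation_amplitude_mm: float = 50.0,
    rotation_amplitude_deg: float = 20.0,
    period_frames: float = 3000.0,
) -> np.ndarray:
    """Smooth rigid motion of a planar marker set: ``(T, M, 3)`` truth (mm).

    Low-frequency sinusoidal translation and rotation along a fixed path;
    ``speed_scale`` reparameterizes time along the *identical* path, so a
    run at scale 2 visits at frame t the pose of the scale-1 run at frame
    2t (the two-speed robot-arm protocol).  Markers remain exactly
    coplanar and pairwise distances are exactly constant.
    """
    if T < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 2 * np.pi, size=6)
    freqs = rng.uniform(0.7, 1.3, size=6) / period_frames
    amp_t = translation_amplitude_mm
    amp_r = np.deg2rad(rotation_amplitude_deg)
    out = np.empty((T, len(board), 3))
    for t in range(T):
        u = speed_scale * t
        trans = amp_t * np.array([
            np.sin(2 * np.pi * freqs[0] * u + phases[0]),
            np.sin(2 * np.pi * freqs[1] * u + phases[1]),
            0.5 * np.sin(2 * np.pi * freqs[2] * u + phases[2]),
        ])
        rotvec = amp_r * np.array([
            np.sin(2 * np.pi * freqs[3] * u + phases[3]),
            np.sin(2 * np.pi * freqs[4] * u + phases[4]),
            np.sin(2 * np.pi * freqs[5] * u + phases[5]),
        ])
        R = Rotation.from_rotvec(rotvec).as_matrix()
        out[t] = board @ R.T + trans
    return out


def simulate_strike(
    n_markers: int = 5,
    peak_speed_ms: float = 1.6,
    duration_s: float = 0.15,
    frame_rate_hz: float = 750.0,
    seed: int = 0,
    body_spacing_mm: float = 35.0,
    curve_radius_mm: float = 350.0,
) -> tuple[np.ndarray, StrikeMetrics]:
    """Strike-like trajectory with an analytically known speed profile.

    The head marker (label 0) moves along a gently curved arc
    (parameterized by arc length, so path length is exact) with speed
    ``v(τ) = v_peak · sin²(π τ / D)`` — a smooth accelerate–decelerate
    profile peaking at ``v_peak`` mid-strike.  Body markers trail the head
    along the same curve at fixed arc-length gaps, pulled forward only
    once the head has advanced past their slack.  Returns the truth array
    ``(T, M, 3)`` in scene mm and the exact head metrics: path
    ``v_peak·D/2``, mean ``v_peak/2``, max ``v_peak``.
    """
    if peak_speed_ms <= 0:
        raise ValueError("peak_speed_ms must be positive")
    rng = np.random.default_rng(seed)
    D = duration_s
    n_steps = int(round(D * frame_rate_hz))
    T = n_steps + 1
    tau = np.arange(T) / frame_rate_hz
    # closed-form arc length of the sin² profile
    s_of_t = peak_speed_ms * (tau / 2.0
                              - D / (4 * np.pi) * np.sin(2 * np.pi * tau / D))
    s_mm = s_of_t * 1000.0

    # unit-speed planar arc of radius R, tilted into 3D by a random rotation
    Rc = curve_radius_mm
    tilt = Rotation.from_rotvec(rng.uniform(-0.3, 0.3, size=3)).as_matrix()
    origin_offset = np.array([0.0, 0.0, -60.0])  # start slightly off-center

    def curve(s: np.ndarray) -> np.ndarray:
        a = s / Rc
        pts = np.stack([Rc * np.sin(a), Rc * (1 - np.cos(a)),
                        np.zeros_like(a)], axis=-1)
        return pts @ tilt.T + origin_offset

    truth = np.empty((T, n_markers, 3))
    for m in range(n_markers):
        gap = m * body_spacing_mm
        s_m = np.maximum(s_mm - gap, 0.0) - gap
        truth[:, m, :] = curve(s_m)
    path_m = peak_speed_ms * D / 2.0
    metrics = StrikeMetrics(
        duration=D,
        path_distance=path_m,
        mean_speed=path_m / D,
        max_velocity=peak_speed_ms,
    )
    return truth, metrics


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _hsv_to_rgb(h_deg: float, s: float, v: float) -> np.ndarray:
    import colorsys

    return np.array(colorsys.hsv_to_rgb((h_deg % 360.0) / 360.0, s, v))


def flicker_factor(t: int, amplitude: float, freq_hz: float,
                   frame_rate_hz: float) -> float:
    """AC-light flicker: V-channel gain ``1 + a·sin(2π f t / rate)``."""
    return 1.0 + amplitude * np.sin(2 * np.pi * freq_hz * t / frame_rate_hz)


def render_frame(
    positions_mm: np.ndarray,
    rig: CameraRig,
    camera_index: int,
    marker_color_hsv: tuple[float, float, float] | list = (120.0, 0.9, 0.9),
    marker_radius_px: float = 4.0,
    background: tuple[float, float, float] = (0.0, 0.0, 0.0),
    distractors: list[tuple[float, float, float, tuple]] | None = None,
    flicker: float = 1.0,
) -> tuple[np.ndarray, list[int]]:
    """Render one camera's view of the markers as an RGB float image.

    Markers are anti-aliased filled disks at their projected positions
    (``marker_color_hsv`` may be one HSV triple or one per marker);
    ``distractors`` are extra ``(u, v, radius, hsv)`` blobs of non-marker
    hue.  ``flicker`` multiplies all channels — equivalently the HSV value
    channel, hue and saturation untouched — before clipping.  Markers
    projecting off-frame (or behind the camera) are simply absent.
    Returns ``(image, painted_pixel_counts)`` where a pixel counts as
    painted when its disk coverage exceeds one half.
    """
    cam = rig[camera_index]
    w = cam.intrinsics.image_width
    h = cam.intrinsics.image_height
    img = np.empty((h, w, 3))
    img[:] = np.asarray(background, dtype=float)
    pos = np.atleast_2d(np.asarray(positions_mm, dtype=float))
    if pos.shape[-1] != 3:
        raise ValueError("positions must be (M, 3)")
    M = len(pos)
    colors = marker_color_hsv
    if isinstance(colors, tuple) or (isinstance(colors, (list, np.ndarray))
                                     and np.ndim(colors) == 1):
        colors = [tuple(colors)] * M

    counts = [0] * M
    blobs: list[tuple[float, float, float, np.ndarray, int | None]] = []
    for m in range(M):
        try:
            uv = project(pos[m], cam)
        except BehindCameraError:
            continue
        blobs.append((float(uv[0]), float(uv[1]), marker_radius_px,
                      _hsv_to_rgb(*colors[m]), m))
    for (u, v, r, hsv) in (distractors or []):
        blobs.append((float(u), float(v), float(r), _hsv_to_rgb(*hsv), None))

    for u, v, r, rgb, m in blobs:
        u0 = max(int(np.floor(u - r - 1)), 0)
        u1 = min(int(np.ceil(u + r + 1)), w - 1)
        v0 = max(int(np.floor(v - r - 1)), 0)
        v1 = min(int(np.ceil(v + r + 1)), h - 1)
        if u1 < u0 or v1 < v0:
            continue
        uu, vv = np.meshgrid(np.arange(u0, u1 + 1), np.arange(v0, v1 + 1))
        d = np.hypot(uu - u, vv - v)
        alpha = np.clip(r + 0.5 - d, 0.0, 1.0)
        patch = img[v0:v1 + 1, u0:u1 + 1, :]
        img[v0:v1 + 1, u0:u1 + 1, :] = (patch * (1 - alpha[..., None])
                                        + rgb * alpha[..., None])
        if m is not None:
            counts[m] = int(np.sum(alpha > 0.5))
    return np.clip(img * flicker, 0.0, 1.0), counts


def render_sequence(
    truth_world: np.ndarray,
    rig: CameraRig,
    marker_color_hsv=(120.0, 0.9, 0.9),
    marker_radius_px: float = 4.0,
    flicker_amplitude: float = 0.0,
    flicker_freq_hz: float = 100.0,
    distractors=None,
) -> list[list[np.ndarray]]:
    """Render all cameras over all timesteps: ``frames[camera][t]``."""
    T = truth_world.shape[0]
    frames = []
    for j in range(len(rig)):
        seq = []
        for t in range(T):
            f = flicker_factor(t, flicker_amplitude, flicker_freq_hz,
                               rig.frame_rate_hz)
            img, _ = render_frame(truth_world[t], rig, j,
                                  marker_color_hsv=marker_color_hsv,
                                  marker_radius_px=marker_radius_px,
                                  distractors=distractors, flicker=f)
            seq.append(img)
        frames.append(seq)
    return frames


# ---------------------------------------------------------------------------
# detection-table corruption (render bypass)
# ---------------------------------------------------------------------------


def corrupt_detections(
    truth_pixels: dict[int, np.ndarray],
    sigma_px: float = 0.0,
    dropout_rate: float = 0.0,
    seed: int = 0,
    shuffle: bool = True,
) -> tuple[DetectionSet, dict[tuple[int, int], dict[int, int]]]:
    """Noisy detection tables straight from truth pixels (no rendering).

    ``truth_pixels[camera]`` is a ``(T, M, 2)`` array (NaN marks an
    invisible marker).  Adds isotropic Gaussian pixel noise and
    independent per-observation dropout; with ``shuffle`` the within-frame
    detection order is randomized so trackers cannot rely on ordering.
    Returns the :class:`~mocap3d.detection.DetectionSet` and an index
    ``{(t, camera): {label: detection_idx}}`` for building initial
    labelings and scoring identity swaps.
    """
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    if not (0 <= dropout_rate < 1):
        raise ValueError("dropout_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cams = sorted(truth_pixels)
    T, M, _ = truth_pixels[cams[0]].shape
    ds = DetectionSet(T, len(cams))
    index: dict[tuple[int, int], dict[int, int]] = {}
    for cam in cams:
        px = truth_pixels[cam]
        noise = rng.normal(0.0, sigma_px, size=px.shape) if sigma_px > 0 \
            else np.zeros_like(px)
        drop = rng.random((T, M)) < dropout_rate
        for t in range(T):
            present = [m for m in range(M)
                       if not drop[t, m] and np.all(np.isfinite(px[t, m]))]
            order = list(present)
            if shuffle and len(order) > 1:
                rng.shuffle(order)
            dets = []
            lut = {}
            for k, m in enumerate(order):
                u, v = px[t, m] + noise[t, m]
                iu, iv = int(np.floor(u)), int(np.floor(v))
                dets.append(Detection((float(u), float(v)), 25,
                                      (iu - 2, iv - 2, iu + 3, iv + 3)))
                lut[m] = k
            ds.set(t, cam, dets)
            index[(t, cam)] = lut
    return ds, index


# ---------------------------------------------------------------------------
# full scenes
# ---------------------------------------------------------------------------


@dataclass
class SyntheticScene:
    """A complete ground-truth bundle for testing the pipeline.

    ``truth`` holds the real marker positions per timestep in the rig's
    world frame (mm); ``truth_pixels[camera]`` their exact noiseless
    projections.  ``frames`` are optional rendered images.  The same seed
    always reproduces the identical scene bit for bit.
    """

    rig: CameraRig
    truth: np.ndarray  # (T, M, 3) mm
    truth_pixels: dict[int, np.ndarray]  # camera -> (T, M, 2)
    seed: int
    params: dict = field(default_factory=dict)
    frames: list | None = None
    true_metrics: StrikeMetrics | None = None

    @property
    def n_timesteps(self) -> int:
        return self.truth.shape[0]

    @property
    def n_markers(self) -> int:
        return self.truth.shape[1]


def _project_truth(rig: CameraRig, truth_world: np.ndarray
                   ) -> dict[int, np.ndarray]:
    T, M, _ = truth_world.shape
    out = {}
    for j in range(len(rig)):
        px = np.full((T, M, 2), np.nan)
        for t in range(T):
            try:
                px[t] = project(truth_world[t], rig[j])
            except BehindCameraError:
                for m in range(M):
                    try:
                        px[t, m] = project(truth_world[t, m], rig[j])
                    except BehindCameraError:
                        pass
        out[j] = px
    return out


def board_scene(
    n_cameras: int = 3,
    T: int = 300,
    size: str = "small",
    speed_scale: float = 1.0,
    standoff_mm: float = 1100.0,
    seed: int = 0,
    moving: bool = True,
    **rig_kwargs,
) -> SyntheticScene:
    """Accuracy-study scene: the five-marker board moved by a robot arm.

    Defaults emulate the accuracy study: three 640×480 cameras at ~1.1 m
    standoff, 750 Hz, small board.  With ``moving=False`` the board holds
    its initial pose (the stationary protocol).
    """
    rig = make_rig(n_cameras=n_cameras, standoff_mm=standoff_mm, seed=seed,
                   **rig_kwargs)
    board, dist = marker_board(size)
    motion = simulate_board_motion(board, T, speed_scale=speed_scale,
                                   seed=seed)
    if not moving:
        motion = np.repeat(motion[:1], T, axis=0)
    truth = np.stack([_scene_to_world(rig, motion[t]) for t in range(T)])
    scene = SyntheticScene(
        rig=rig, truth=truth, truth_pixels=_project_truth(rig, truth),
        seed=seed,
        params={"kind": "board", "size": size, "speed_scale": speed_scale,
                "n_cameras": n_cameras, "T": T, "moving": moving,
                "reference_distances": dist.tolist()},
    )
    return scene


def strike_scene(
    n_cameras: int = 5,
    peak_speed_ms: float = 1.6,
    duration_s: float = 0.15,
    frame_rate_hz: float = 750.0,
    n_markers: int = 5,
    standoff_mm: float = 1100.0,
    seed: int = 0,
    **rig_kwargs,
) -> SyntheticScene:
    """Strike scene: five cameras, head + body markers, known peak speed."""
    rig = make_rig(n_cameras=n_cameras, standoff_mm=standoff_mm,
                   frame_rate_hz=frame_rate_hz, seed=seed, **rig_kwargs)
    truth_scene, metrics = simulate_strike(
        n_markers=n_markers, peak_speed_ms=peak_speed_ms,
        duration_s=duration_s, frame_rate_hz=frame_rate_hz, seed=seed)
    T = truth_scene.shape[0]
    truth = np.stack([_scene_to_world(rig, truth_scene[t]) for t in range(T)])
    return SyntheticScene(
        rig=rig, truth=truth, truth_pixels=_project_truth(rig, truth),
        seed=seed, true_metrics=metrics,
        params={"kind": "strike", "peak_speed_ms": peak_speed_ms,
                "duration_s": duration_s, "frame_rate_hz": frame_rate_hz,
                "n_cameras": n_cameras, "n_markers": n_markers},
    )


def save_scene(scene: SyntheticScene, directory) -> None:
    """Write a scene bundle: calibration, truth CSVs, manifest.

    Layout: ``calibration.json``, ``truth.csv`` (t,label,x,y,z),
    ``truth_pixels_camNN.csv`` per camera, ``manifest.json`` with seed and
    parameters; rendered frames (if any) as ``images/camNN/frame_*.png``.
    """
    import pandas as pd

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_rig(scene.rig, d / "calibration.json")
    T, M, _ = scene.truth.shape
    rows = [{"t": t, "label": m, "x": scene.truth[t, m, 0],
             "y": scene.truth[t, m, 1], "z": scene.truth[t, m, 2]}
            for t in range(T) for m in range(M)]
    pd.DataFrame(rows).to_csv(d / "truth.csv", index=False)
    for j, px in scene.truth_pixels.items():
        rows = [{"t": t, "label": m, "u": px[t, m, 0], "v": px[t, m, 1]}
                for t in range(T) for m in range(M)]
        pd.DataFrame(rows).to_csv(d / f"truth_pixels_cam{j:02d}.csv",
                                  index=False)
    manifest = {"seed": scene.seed, "params": scene.params,
                "n_timesteps": T, "n_markers": M}
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    if scene.frames is not None:
        import imageio.v3 as iio

        for j, seq in enumerate(scene.frames):
            cam_dir = d / "images" / f"cam{j:02d}"
            cam_dir.mkdir(parents=True, exist_ok=True)
            for t, img in enumerate(seq):
                iio.imwrite(cam_dir / f"frame_{t:06d}.png",
                            (np.clip(img, 0, 1) * 255).astype(np.uint8))
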