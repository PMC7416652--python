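"""Project layout, configuration and the staged offline pipeline.

The pipeline reproduces the processing order of the capture system:
``simulate → detect → label → track → triangulate → smooth → analyze``.
Every stage reads and writes only documented CSV/JSON/PLY artifacts
inside a project directory::

    project/
      config.json|yaml
      calibration/calibration.json
      images/camNN/frame_*.png      (optional; detect can run from images)
      detections/detections.csv
      tracks/labeling.csv  tracks.csv
      triangulated/trajectory.csv  trajectory.ply
      analysis/metrics.csv  report.json

Reruns with identical inputs and seed are bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .camera import load_rig, save_rig
from .detection import ColorRangeHSV, DetectionSet
from .tracking import InitialLabeling, snap_labeling, track_markers
from .triangulation import Trajectory3D, triangulate_sequence, export_ply
from .analysis import (smooth_trajectory, velocity_profile, mask_by_velocity,
                       strike_metrics, interpoint_errors)
from .synthetic import board_scene, strike_scene, corrupt_detections, save_scene

logger = logging.getLogger("mocap3d")

STAGES = ["simulate", "detect", "label", "track", "triangulate", "smooth",
          "analyze"]


@dataclass
class ProjectConfig:
    """All tunable parameters of a processing project."""

    project_dir: str = "."
    seed: int = 0
    # simulate
    scene_kind: str = "strike"  # or "board"
    n_cameras: int = 5
    n_timesteps: int = 120
    peak_speed_ms: float = 1.6
    duration_s: float = 0.15
    noise_px: float = 0.0
    dropout: float = 0.0
    # detection
    h_lo: float = 100.0
    h_hi: float = 140.0
    s_lo: float = 0.3
    s_hi: float = 1.0
    v_lo: float = 0.3
    v_hi: float = 1.0
    kernel_size: int = 3
    min_area: int = 4
    # tracking
    gate: float = 30.0
    q: float = 1.0
    r: float = 1.0
    max_coast: int = 15
    # triangulation
    min_cameras: int = 2
    require_all: bool = False
    tol: float = 1e-10
    max_iter: int = 20
    # smoothing
    smooth_q: float = 0.01
    smooth_r: float = 1.0
    # analysis
    velocity_threshold: float = 2.5
    window_start: int = 0
    window_end: int = -1  # -1: last frame
    poly_degree: int = 4
    head_label: int = 0

    def path(self, *parts) -> Path:
        return Path(self.project_dir).joinpath(*parts)


_RANGES = {
    "seed": (0, 2**31 - 1),
    "n_cameras": (2, 64),
    "n_timesteps": (2, 10**7),
    "kernel_size": (1, 99),
    "min_area": (1, 10**6),
    "gate": (1e-9, 1e6),
    "q": (0.0, 1e9),
    "r": (1e-12, 1e9),
    "max_coast": (0, 10**6),
    "min_cameras": (2, 64),
    "tol": (0.0, 1.0),
    "max_iter": (1, 10**4),
    "smooth_q": (0.0, 1e9),
    "smooth_r": (1e-12, 1e9),
    "velocity_threshold": (1e-9, 1e9),
    "poly_degree": (0, 20),
    "noise_px": (0.0, 1e3),
    "dropout": (0.0, 0.999),
}


def validate_config(config: ProjectConfig) -> list[str]:
    """Return a list of human-readable violations (empty iff valid)."""
    problems: list[str] = []
    for name, (lo, hi) in _RANGES.items():
        val = getattr(config, name)
        if not (lo <= val <= hi):
            problems.append(f"{name}: value {val} outside [{lo}, {hi}]")
    if config.kernel_size % 2 == 0:
        problems.append("kernel_size: must be odd")
    if config.scene_kind not in ("strike", "board"):
        problems.append("scene_kind: must be 'strike' or 'board'")
    if not (0 <= config.s_lo <= config.s_hi <= 1):
        problems.append("s_lo/s_hi: need 0 <= s_lo <= s_hi <= 1")
    if not (0 <= config.v_lo <= config.v_hi <= 1):
        problems.append("v_lo/v_hi: need 0 <= v_lo <= v_hi <= 1")
    calib = config.path("calibration", "calibration.json")
    if calib.exists():
        try:
            load_rig(calib)
        except Exception as e:  # noqa: BLE001 - report, don't raise
            problems.append(f"calibration: {e}")
    return problems


def load_config(path) -> ProjectConfig:
    """Read a JSON or YAML config file; unknown keys are rejected."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    fields_ = ProjectConfig.__dataclass_fields__
    unknown = set(data) - set(fields_)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    # coerce scalar types (YAML 1.1 parses '1e-10' as a string)
    defaults = ProjectConfig()
    for k, v in list(data.items()):
        want = type(getattr(defaults, k))
        if want in (int, float, bool) and not isinstance(v, want):
            data[k] = want(float(v)) if want is not bool else bool(v)
    cfg = ProjectConfig(**data)
    if not data.get("project_dir"):
        cfg.project_dir = str(Path(path).parent)
    return cfg


def save_config(config: ProjectConfig, path) -> None:
    p = Path(path)
    payload = asdict(config)
    with open(p, "w") as fh:
        if p.suffix in (".yaml", ".yml"):
            yaml.safe_dump(payload, fh, sort_keys=True)
        else:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


class MissingArtifactError(FileNotFoundError):
    def __init__(self, stage: str, path: Path):
        self.stage = stage
        self.path = path
        super().__init__(
            f"stage '{stage}' requires missing artifact: {path}"
        )


def _require(stage: str, path: Path) -> Path:
    if not path.exists():
        raise MissingArtifactError(stage, path)
    return path


def run_pipeline(config: ProjectConfig, stages: list[str] | None = None
                 ) -> dict:
    """Run the requested stages in order; returns the run report.

    The report (also written to ``analysis/report.json``) records the
    package version, seed, parameters, and per-stage counts.
    """
    stages = stages or STAGES
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    stages = [s for s in STAGES if s in stages]
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    root = Path(config.project_dir)
    report: dict = {"version": __version__, "seed": config.seed,
                    "parameters": asdict(config), "stages": {}}

    for sub in ("calibration", "detections", "tracks", "triangulated",
                "analysis"):
        (root / sub).mkdir(parents=True, exist_ok=True)

    for stage in stages:
        logger.info("stage: %s", stage)
        report["stages"][stage] = _STAGE_FNS[stage](config)

    report_path = root / "analysis" / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _stage_simulate(cfg: ProjectConfig) -> dict:
    if cfg.scene_kind == "board":
        scene = board_scene(n_cameras=cfg.n_cameras, T=cfg.n_timesteps,
                            seed=cfg.seed)
    else:
        scene = strike_scene(n_cameras=cfg.n_cameras,
                             peak_speed_ms=cfg.peak_speed_ms,
                             duration_s=cfg.duration_s, seed=cfg.seed)
    save_scene(scene, cfg.path("scene"))
    save_rig(scene.rig, cfg.path("calibration", "calibration.json"))
    return {"kind": cfg.scene_kind, "n_timesteps": scene.n_timesteps,
            "n_markers": scene.n_markers, "n_cameras": len(scene.rig)}


def _load_truth_pixels(cfg: ProjectConfig) -> dict[int, np.ndarray]:
    scene_dir = cfg.path("scene")
    out = {}
    for f in sorted(scene_dir.glob("truth_pixels_cam*.csv")):
        j = int(f.stem.replace("truth_pixels_cam", ""))
        df = pd.read_csv(f)
        T = int(df["t"].max()) + 1
        M = int(df["label"].max()) + 1
        px = np.full((T, M, 2), np.nan)
        px[df["t"], df["label"], 0] = df["u"]
        px[df["t"], df["label"], 1] = df["v"]
        out[j] = px
    return out


def _stage_detect(cfg: ProjectConfig) -> dict:
    """Detect markers; from rendered images if present, else the fast
    render-bypass path (noisy detections straight from truth pixels)."""
    images = cfg.path("images")
    det_path = cfg.path("detections", "detections.csv")
    if images.exists() and any(images.iterdir()):
        from .detection import detect_sequence, load_image_sequence

        cams = sorted(images.glob("cam*"))
        frames = [load_image_sequence(c) for c in cams]
        rng = ColorRangeHSV(cfg.h_lo, cfg.h_hi, cfg.s_lo, cfg.s_hi,
                            cfg.v_lo, cfg.v_hi)
        ds = detect_sequence(frames, rng, kernel_size=cfg.kernel_size,
                             min_area=cfg.min_area)[0]
    else:
        _require("detect", cfg.path("scene", "manifest.json"))
        truth_px = _load_truth_pixels(cfg)
        ds, _ = corrupt_detections(truth_px, sigma_px=cfg.noise_px,
                                   dropout_rate=cfg.dropout, seed=cfg.seed)
    ds.to_csv(det_path)
    df = ds.to_dataframe()
    return {"n_detections": int(len(df)),
            "frames_per_camera": {int(c): int(g["t"].nunique())
                                  for c, g in df.groupby("camera")}}


def _stage_label(cfg: ProjectConfig) -> dict:
    """Snap provided clicks (or truth pixels at t0) to nearest detections."""
    det_path = _require("label", cfg.path("detections", "detections.csv"))
    ds = DetectionSet.from_csv(det_path)
    clicks_path = cfg.path("tracks", "clicks.csv")
    if clicks_path.exists():
        cdf = pd.read_csv(clicks_path)
        t0 = int(cdf["t"].iloc[0]) if "t" in cdf.columns else 0
        clicks = {}
        for _, r in cdf.iterrows():
            clicks.setdefault(int(r["camera"]), {})[int(r["label"])] = \
                (float(r["u"]), float(r["v"]))
    else:
        truth_px = _load_truth_pixels(cfg)
        t0 = 0
        clicks = {}
        for j, px in truth_px.items():
            clicks[j] = {m: tuple(px[t0, m]) for m in range(px.shape[1])
                         if np.all(np.isfinite(px[t0, m]))}
    lab = snap_labeling(ds, t0, clicks)
    rows = [{"camera": cam, "label": l, "u": ds.get(t0, cam)[i].centroid[0],
             "v": ds.get(t0, cam)[i].centroid[1]}
            for cam, m in lab.assignments.items() for l, i in m.items()]
    pd.DataFrame(rows).to_csv(cfg.path("tracks", "labeling.csv"), index=False)
    with open(cfg.path("tracks", "labeling_meta.json"), "w") as fh:
        json.dump({"t0": t0, "assignments": {str(c): m for c, m in
                                             lab.assignments.items()}}, fh)
        fh.write("\n")
    return {"t0": t0, "n_labels": len(lab.labels())}


def _stage_track(cfg: ProjectConfig) -> dict:
    det_path = _require("track", cfg.path("detections", "detections.csv"))
    meta_path = _require("track", cfg.path("tracks", "labeling_meta.json"))
    ds = DetectionSet.from_csv(det_path)
    meta = json.loads(meta_path.read_text())
    labeling = InitialLabeling(
        t0=int(meta["t0"]),
        assignments={int(c): {int(l): int(i) for l, i in m.items()}
                     for c, m in meta["assignments"].items()},
    )
    ts = track_markers(ds, labeling, gate=cfg.gate, q=cfg.q, r=cfg.r,
                       max_coast=cfg.max_coast)
    ts.to_csv(cfg.path("tracks", "tracks.csv"))
    df = ts.to_dataframe()
    return {"n_rows": int(len(df)),
            "measured_fraction": float((df["status"] == "measured").mean())}


def _stage_triangulate(cfg: ProjectConfig) -> dict:
    from .tracking import TrackSet

    tracks_path = _require("triangulate", cfg.path("tracks", "tracks.csv"))
    calib = _require("triangulate",
                     cfg.path("calibration", "calibration.json"))
    rig = load_rig(calib)
    ts = TrackSet.from_csv(tracks_path)
    traj = triangulate_sequence(ts, rig, min_cameras=cfg.min_cameras,
                                require_all=cfg.require_all, tol=cfg.tol,
                                max_iter=cfg.max_iter)
    traj.to_csv(cfg.path("triangulated", "trajectory.csv"))
    export_ply(traj, cfg.path("triangulated", "trajectory.ply"))
    return {"n_valid": int(traj.valid.sum()),
            "n_total": int(traj.valid.size)}


def _stage_smooth(cfg: ProjectConfig) -> dict:
    calib = _require("smooth", cfg.path("calibration", "calibration.json"))
    traj_path = _require("smooth", cfg.path("triangulated", "trajectory.csv"))
    rig = load_rig(calib)
    traj = Trajectory3D.from_csv(traj_path, rig.frame_rate_hz)
    sm = smooth_trajectory(traj, q=cfg.smooth_q, r=cfg.smooth_r)
    sm.to_csv(cfg.path("triangulated", "trajectory_smoothed.csv"))
    return {"n_valid": int(sm.valid.sum())}


def _stage_analyze(cfg: ProjectConfig) -> dict:
    calib = _require("analyze", cfg.path("calibration", "calibration.json"))
    rig = load_rig(calib)
    smoothed = cfg.path("triangulated", "trajectory_smoothed.csv")
    traj_path = smoothed if smoothed.exists() else _require(
        "analyze", cfg.path("triangulated", "trajectory.csv"))
    traj = Trajectory3D.from_csv(traj_path, rig.frame_rate_hz)
    t_end = cfg.window_end if cfg.window_end >= 0 else traj.n_timesteps - 1
    out: dict = {}
    speeds, step_valid = velocity_profile(traj, cfg.head_label)
    keep = mask_by_velocity(speeds, step_valid, cfg.velocity_threshold)
    pd.DataFrame({"t": np.arange(len(speeds)), "speed_ms": speeds,
                  "step_valid": step_valid, "keep": keep}).to_csv(
        cfg.path("analysis", "velocity.csv"), index=False)
    from .plots import plot_velocity

    plot_velocity(speeds, keep, cfg.path("analysis", "velocity.png"),
                  threshold=cfg.velocity_threshold)
    try:
        sm = strike_metrics(traj, cfg.head_label, (cfg.window_start, t_end),
                            cfg.velocity_threshold)
        pd.DataFrame([{
            "trial": 1, "subject": "synthetic",
            "duration_s": sm.duration, "distance_m": sm.path_distance,
            "speed_ms": sm.mean_speed, "max_velocity_ms": sm.max_velocity,
        }]).to_csv(cfg.path("analysis", "metrics.csv"), index=False)
        out["metrics"] = {"duration_s": sm.duration,
                          "distance_m": sm.path_distance,
                          "speed_ms": sm.mean_speed,
                          "max_velocity_ms": sm.max_velocity}
    except ValueError as e:
        out["metrics_error"] = str(e)
    if cfg.scene_kind == "board":
        manifest = cfg.path("scene", "manifest.json")
        if manifest.exists():
            ref = np.asarray(json.loads(manifest.read_text())["params"]
                             ["reference_distances"])
            _, summary = interpoint_errors(traj, ref)
            summary.to_csv(cfg.path("analysis", "interpoint_errors.csv"),
                           index=False)
            out["mean_abs_interpoint_error_mm"] = float(
                summary["mean_abs"].mean())
    return out


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "detect": _stage_detect,
    "label": _stage_label,
    "track": _stage_track,
    "triangulate": _stage_triangulate,
    "smooth": _stage_smooth,
    "analyze": _stage_analyze,
}
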