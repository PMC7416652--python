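# mocap3d

Offline 3D reconstruction of colored markers from synchronized
multi-camera high-speed video, aimed at fast animal behavior — e.g. snake
strikes, which complete in well under 200 ms and need capture rates around
750 Hz to resolve.

Given per-camera image sequences (or pre-extracted 2D detection tables), a
rig calibration, and a one-timestep manual marker labeling, the package
produces labeled 3D marker trajectories and strike kinematics:

1. **Detection** — HSV color thresholding (inclusive bounds, hue
   wrap-around), morphological open/close cleanup, and 8-connected
   component centroiding turn each frame into a set of 2D observations
   `V_{t,j}` per timestep `t` and camera `j`.
2. **Tracking** — per camera, a constant-velocity Kalman filter predicts
   each labeled marker one frame ahead and the Hungarian (Munkres–Kuhn)
   algorithm assigns predictions to detections under a distance gate.
   The filter only resolves correspondence: reported positions are always
   the raw detection centroids. Alternative correspondence engines plug in
   through a registry (`register_correspondence`).
3. **Triangulation** — observations are undistorted (Brown–Conrady model,
   fixed-point inversion), then each 3D point `Ŝ_t` is solved by DLT/SVD
   and refined by *optimal correction*: the observed pixels are
   translocated minimally so all camera rays intersect, equivalently the
   point minimizing `Σ_j ‖x_j − π_j(X)‖²` (the reprojection error). A
   camera-subset fallback handles occlusion; camera 0 anchors the world
   frame.
4. **Analysis** — interpoint-distance error against a reference geometry,
   total-least-squares plane fit, forward–backward (RTS) smoothing,
   per-step velocity `v_t = ‖p_t − p_{t−1}‖·f`, velocity-threshold masking
   of identity-swap artifacts (default 2.5 m/s), and per-strike metrics
   (duration, path distance, mean speed, max velocity) with group
   aggregation.

A first-class synthetic module generates camera rigs, a five-marker
planar accuracy board, rigid board motion, strike-like trajectories with
an analytically known speed profile, rendered frames with light flicker,
and noisy detection tables — all bit-reproducible from a seed — so every
stage is testable against exact ground truth.

## Worked example

Simulate a 1.6 m/s strike seen by five 640×480 cameras at 750 Hz with
0.5 px detection noise, then run the full pipeline:

```python
import numpy as np
from mocap3d import (strike_scene, corrupt_detections, InitialLabeling,
                     track_markers, triangulate_sequence,
                     smooth_trajectory, strike_metrics)

scene = strike_scene(peak_speed_ms=1.6, duration_s=0.15, seed=41)
dets, index = corrupt_detections(scene.truth_pixels, sigma_px=0.5, seed=41)
labeling = InitialLabeling(
    t0=0, assignments={c: dict(index[(0, c)]) for c in range(5)})
tracks = track_markers(dets, labeling)
traj = triangulate_sequence(tracks, scene.rig)
smoothed = smooth_trajectory(traj, q=0.01, r=0.5)
m = strike_metrics(smoothed, label=0, window=(0, traj.n_timesteps - 1))
print(f"duration {m.duration:.3f} s  path {m.path_distance:.3f} m  "
      f"mean {m.mean_speed:.2f} m/s  max {m.max_velocity:.2f} m/s")
```

prints

```
duration 0.149 s  path 0.121 m  mean 0.81 m/s  max 1.62 m/s
```

— the generated strike peaks at 1.6 m/s and covers `v_peak·D/2 = 0.12` m,
so the recovered maximum (1.62 m/s) is within 2% of truth at this noise
level. The same stages are available as a CLI
(`mocap3d simulate|detect|label|track|triangulate|smooth|analyze`)
operating on a project directory of CSV/JSON/PLY artifacts.

Aggregating the bundled 15-trial boa strike table:

```python
from mocap3d import aggregate_trials
from mocap3d.datasets import strike_trials

df = strike_trials()
per_subject, overall = aggregate_trials(df, grouping=df["subject"])
print(overall.round(4).to_dict())
# {'duration_s': 0.1396, 'distance_m': 0.1522,
#  'speed_ms': 1.1208, 'max_velocity_ms': 1.6376}
```

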