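# Methods

This note documents the models, parameters and numerical choices behind
`mocap3d`, and what the synthetic test scenes do and do not establish
about real captures.

## Camera model and undistortion

Each camera is a pinhole with zero skew (`fx, fy, cx, cy` in pixels) and
5-coefficient Brown–Conrady distortion (`k1, k2, k3` radial on
`r² = x²+y²` of normalized coordinates; `p1, p2` tangential). Pixel
coordinates are continuous with the origin at the top-left pixel
*center*, x right, y down; integer coordinates address pixel centers, so
the centroid of a symmetric blob lands exactly on its geometric center.
World units are millimeters; time is counted in frames internally and
converted to seconds only at analysis boundaries.

Camera 0 of every rig carries the identity pose and defines the world
frame; the calibration reader rejects files violating this anchor
convention, and the synthetic rig builder re-anchors its arc of cameras
accordingly.

Undistortion inverts the distortion map by fixed-point iteration on
normalized coordinates (`x ← x + (x_d − D(x))`), at most 20 iterations,
tolerance 1e-9; convergence status and the residual are available via
`full_output=True`. For the mild distortions typical of machine-vision
lenses (|r| < 0.5) the round trip distort∘undistort is exact to below
1e-6 px. Pose recovery from known 3D↔2D correspondences (used to build
synthetic calibrations) is algebraic DLT resectioning with Hartley-style
isotropic pre-normalization of both point sets, followed by projection of
the rotation block onto the nearest proper rotation via SVD.

## Detection

HSV thresholding uses hue in degrees on [0, 360) with wrap-around ranges
(`h_lo > h_hi` selects the arc through 0°), saturation and value in
[0, 1], all bounds inclusive. Cleanup is morphological opening followed
by closing with a square kernel (default 3): opening removes sub-kernel
specks, closing re-joins markers optically split by glare or shadow.
Components are 8-connected so diagonally touching fragments merge; the
centroid is the unweighted mean of member pixel coordinates; blobs under
`min_area` (default 4 px) are dropped. Multiple color ranges (e.g. blue
body markers and a red head marker) are processed fully independently
and only merged after triangulation.

## Tracking

Identity is maintained per camera from a single user-labeled timestep
`t0`. The per-marker state is `(u, v, du, dv)` with constant-velocity
transition (Δt = 1 frame), white-acceleration process noise `q·G`
(default q = 1 px²/frame³) and isotropic measurement noise (r = 1 px²);
tracks start with zero velocity and 100× inflated velocity covariance.
At each frame the Hungarian algorithm minimizes total
prediction-to-detection distance; pairs beyond the gate (default 30 px)
are forbidden. Assigned tracks record the raw centroid (never the filter
mean); unassigned tracks coast on the prediction and are marked lost
after `max_coast` = 15 consecutive coasting frames, while still
competing for detections inside the gate so they recover on reappearance.
When `t0 > 0` the earlier frames are tracked by an independent backward
pass with time-reversed dynamics. Tracking is fully deterministic.

The tracker itself is registered as the `"kalman_hungarian"`
correspondence engine; any callable with the same signature can be
registered and its output is validated for per-camera label uniqueness.
Cross-camera correspondence is carried entirely by the shared label
space fixed at `t0` — no epipolar verification stage is attempted.

## Triangulation and optimal correction

Pixels are undistorted, normalized by the intrinsics, and the DLT system
(two cross-product rows per camera) is solved by SVD; the solution is the
right singular vector of the smallest singular value, with explicit
rank-deficiency and point-at-infinity guards. The optimal-correction
stage is specified by its optimum: it returns the 3D point minimizing
the summed squared reprojection error, computed as a damped Gauss–Newton
iteration on the 3D point initialized at the DLT solution. Steps that
would increase the cost are halved, so the total squared correction is
non-increasing; iteration stops when its change falls below `tol`
(1e-10 px²) or after `max_iter` = 20 (the best iterate is then returned
flagged rather than raising, so batch sequences never die mid-run). The
corrected pixels are defined as the reprojections of the returned point,
whose rays intersect there by construction. On noisy inputs the result
matches an independent nonlinear-least-squares minimizer to below
1e-3 mm, and it typically converges in a couple of iterations.

Per timestep and label, all cameras whose track status is *measured* are
used (subset fallback under occlusion) provided at least `min_cameras`
(default 2) remain; with `require_all` set, any missing camera
invalidates the point instead. Invalidity is data (a mask), not an
exception. DLT rows are unweighted after correction.

## Smoothing and kinematics

The forward–backward filter is a constant-velocity Kalman filter plus
Rauch–Tung–Striebel backward pass, independent per marker and axis, with
`q` in mm²/frame³ (default 0.01 — tolerant of strike-scale accelerations
at 750 Hz) and `r` in mm² (default 1.0, of the order of single-pixel
triangulation noise at ~1 m standoff). The initial velocity comes from
two-point differencing, which makes the smoother exact on
model-consistent (linear) signals. Invalid frames are bridged by
prediction but stay flagged.

Per-step speed is `v_t = ‖p_t − p_{t−1}‖·f` (mm → m/s at frame rate
`f`). Steps above the velocity threshold (default 2.5 m/s, chosen above
any plausible strike speed for this body size) mark both endpoint
samples suspect; a sample is dropped only when *all* of its valid
incident steps offend, so a single teleported sample is removed while
its neighbors survive. The strike window (first forward motion to start
of head retraction) is an explicit user input — behavioral segmentation
is not algorithmically defined here and no auto-detector is shipped.
Strike metrics satisfy `mean_speed · duration = path_distance` by
construction. Velocity-vs-time curves are least-squares polynomials
(default degree 4); the group-level "average best fit" pools trials
after aligning each to its window start.

The capture-buffer utility is the exact byte product
`n_cameras · width · height · bytes_per_pixel · rate · seconds` (RGB8 =
3 B/px, Bayer BG8 = 1 B/px), with no container overhead.

## Synthetic scenes

The generator stands in for the capture hardware and provides exact
ground truth:

* **Rigs** — cameras evenly spaced on a horizontal arc at the standoff
  radius, aimed at a common target, re-anchored to camera 0. Defaults:
  640×480 px, 800 px focal length, 750 Hz, 1100 mm standoff. The
  generic default arc is 60°; accuracy-study scenes use 90° because an
  accuracy rig surrounds its working volume, and depth conditioning at
  sub-pixel noise depends strongly on that spread.
* **Board** — the five-marker planar geometry (corner square of side
  72 mm / 84 mm, fifth marker at an edge midpoint), fixed by its distance
  matrix up to isometry. Board motion is low-frequency sinusoidal rigid
  translation + rotation; `speed_scale` reparameterizes time along the
  identical path, mirroring a two-speed robot-arm protocol.
* **Strikes** — the head marker follows a gently curved arc
  (parameterized by arc length) with speed `v(τ) = v_peak·sin²(πτ/D)`,
  giving closed-form path length `v_peak·D/2`, mean `v_peak/2` and max
  `v_peak`; body markers trail at fixed arc-length gaps. Defaults sit in
  the observed boid-strike range (peak ≈ 1.3–2.3 m/s, duration
  ≈ 0.08–0.2 s).
* **Rendering** — anti-aliased disks over a dark background; a pixel
  counts as painted at coverage > ½. Light flicker multiplies all RGB
  channels by `1 + a·sin(2πft/rate)` (equivalently the HSV value
  channel; hue and saturation untouched), defaults a = 0.15, f = 100 Hz.
  Distractor blobs of non-marker hue are available for false-positive
  tests.
* **Detection bypass** — `corrupt_detections` adds Gaussian pixel noise
  and per-observation dropout directly to the exact projections and
  shuffles within-frame order, for triangulation/tracking tests without
  the rendering cost.

Everything is bit-reproducible from its seed.

What the synthetic scenes do **not** emulate: real lens calibration
error, correlated (non-Gaussian) centroid drift from illumination and
viewing angle, motion blur, marker deformation on a bending body, and
real occlusion geometry. Passing the synthetic recovery tests therefore
demonstrates correctness of the algorithms under their stated noise
models, not field accuracy of a particular rig.

## Test problem sizes

The suite exercises board scenes of 150–300 frames and strike scenes of
≈ 60–115 frames across tens of seeds, with oracle comparisons (exhaustive
assignment search up to 6×6; multi-start nonlinear least squares for
triangulation) on 100 random cases each. These sizes make the full suite
and the acceptance script each run in well under a minute on one CPU
while keeping Monte-Carlo bounds comfortably away from their thresholds.

## Known limitations

* No bundle adjustment: camera parameters are trusted as given.
* The two-view closed-form (polynomial) optimal triangulation is not
  implemented; the iterative scheme is used for all camera counts.
* No automatic strike segmentation; the analysis window is user-chosen.
* The tracker has no re-identification across long occlusions beyond
  gate recapture, and no epipolar consistency check between cameras.
* Feature-based multi-camera self-calibration from calibration imagery
  is out of scope; calibrations are loaded from file (or synthesized by
  resectioning from known correspondences).
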