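"""Marker detection: HSV thresholding, morphological cleanup, centroiding.

Frames are RGB arrays (uint8 or float in [0, 1]).  Hue is measured in
degrees on [0, 360) with wrap-around ranges permitted; saturation and
value are fractions in [0, 1].  All range bounds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2hsv

__all__ = [
    "ColorRangeHSV",
    "Detection",
    "DetectionSet",
    "threshold_hsv",
    "clean_binary",
    "find_markers",
    "detect_sequence",
]


@dataclass(frozen=True)
class ColorRangeHSV:
    """Inclusive HSV box; ``h_lo > h_hi`` selects the arc through 0°."""

    h_lo: float
    h_hi: float
    s_lo: float = 0.0
    s_hi: float = 1.0
    v_lo: float = 0.0
    v_hi: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.s_lo > self.s_hi:
            raise ValueError("empty saturation range (s_lo > s_hi)")
        if self.v_lo > self.v_hi:
            raise ValueError("empty value range (v_lo > v_hi)")
        for h in (self.h_lo, self.h_hi):
            if not (0 <= h < 360):
                raise ValueError("hue bounds must lie in [0, 360)")

    def hue_mask(self, h_deg: np.ndarray) -> np.ndarray:
        if self.h_lo <= self.h_hi:
            return (h_deg >= self.h_lo) & (h_deg <= self.h_hi)
        return (h_deg >= self.h_lo) | (h_deg <= self.h_hi)


@dataclass(frozen=True)
class Detection:
    """A connected blob of thresholded pixels.

    ``centroid`` is the unweighted mean of member pixel coordinates as
    ``(u, v)`` = (column, row); ``bbox`` is ``(u_min, v_min, u_max, v_max)``
    inclusive.
    """

    centroid: tuple[float, float]
    area: int
    bbox: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("detection area must be >= 1")
        u, v = self.centroid
        u0, v0, u1, v1 = self.bbox
        if not (u0 <= u <= u1 and v0 <= v <= v1):
            raise ValueError("centroid outside bounding box")


class DetectionSet:
    """Per-timestep, per-camera lists of detections (the 2D observations)."""

    def __init__(self, n_timesteps: int, n_cameras: int):
        self.n_timesteps = int(n_timesteps)
        self.n_cameras = int(n_cameras)
        self._data: dict[tuple[int, int], list[Detection]] = {}

    def set(self, t: int, camera: int, detections: list[Detection]) -> None:
        self._check(t, camera)
        self._data[(t, camera)] = list(detections)

    def get(self, t: int, camera: int) -> list[Detection]:
        self._check(t, camera)
        return self._data.get((t, camera), [])

    def _check(self, t: int, camera: int) -> None:
        if not (0 <= t < self.n_timesteps):
            raise IndexError(f"timestep {t} outside [0, {self.n_timesteps})")
        if not (0 <= camera < self.n_cameras):
            raise IndexError(f"camera {camera} outside [0, {self.n_cameras})")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (t, cam), dets in sorted(self._data.items()):
            for k, d in enumerate(dets):
                rows.append(
                    {"t": t, "camera": cam, "marker_idx": k,
                     "u": d.centroid[0], "v": d.centroid[1], "area": d.area}
                )
        return pd.DataFrame(
            rows, columns=["t", "camera", "marker_idx", "u", "v", "area"]
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, *, n_timesteps: int | None = None,
                       n_cameras: int | None = None) -> "DetectionSet":
        if n_timesteps is None:
            n_timesteps = int(df["t"].max()) + 1 if len(df) else 0
        if n_cameras is None:
            n_cameras = int(df["camera"].max()) + 1 if len(df) else 0
        ds = cls(n_timesteps, n_cameras)
        for (t, cam), grp in df.groupby(["t", "camera"]):
            grp = grp.sort_values("marker_idx")
            dets = []
            for _, r in grp.iterrows():
                u, v = float(r["u"]), float(r["v"])
                a = int(r["area"]) if r["area"] >= 1 else 1
                iu, iv = int(round(u)), int(round(v))
                dets.append(Detection((u, v), a, (min(iu, int(np.floor(u))),
                                                  min(iv, int(np.floor(v))),
                                                  max(iu, int(np.ceil(u))),
                                                  max(iv, int(np.ceil(v))))))
            ds.set(int(t), int(cam), dets)
        return ds

    @classmethod
    def from_csv(cls, path, **kw) -> "DetectionSet":
        return cls.from_dataframe(pd.read_csv(path, float_precision="round_trip"), **kw)


def _as_float_rgb(frame: np.ndarray) -> np.ndarray:
    arr = np.asarray(frame)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("frame must be an RGB image of shape (H, W, 3)")
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    return np.clip(arr.astype(float), 0.0, 1.0)


def threshold_hsv(
    frame: np.ndarray,
    color_range: ColorRangeHSV,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Binary image of pixels whose HSV value lies inside the range.

    A pixel is on iff hue, saturation and value all fall inside their
    (inclusive) bounds and the optional setup mask is on there.
    """
    rgb = _as_float_rgb(frame)
    hsv = rgb2hsv(rgb)
    h = hsv[..., 0] * 360.0
    s = hsv[..., 1]
    v = hsv[..., 2]
    on = (
        color_range.hue_mask(h)
        & (s >= color_range.s_lo) & (s <= color_range.s_hi)
        & (v >= color_range.v_lo) & (v <= color_range.v_hi)
    )
    if mask is not None:
        m = np.asarray(mask).astype(bool)
        if m.shape != on.shape:
            raise ValueError(
                f"mask shape {m.shape} does not match frame {on.shape}"
            )
        on &= m
    return on


def clean_binary(binary: np.ndarray, kernel_size: int = 3) -> np.ndarray:
    """Morphological opening then closing with a square structuring element.

    Opening removes specks smaller than the kernel; closing re-joins marker
    fragments separated by thin gaps (a split marker bridged back together).
    """
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be a positive odd integer")
    b = np.asarray(binary).astype(bool)
    if kernel_size == 1:
        return b.copy()
    selem = np.ones((kernel_size, kernel_size), dtype=bool)
    opened = ndimage.binary_opening(b, structure=selem)
    # pad before closing so dilation at the border is not clipped
    pad = kernel_size
    padded = np.pad(opened, pad, mode="constant")
    closed = ndimage.binary_closing(padded, structure=selem)
    return closed[pad:-pad, pad:-pad]


_EIGHT = np.ones((3, 3), dtype=bool)


def find_markers(binary: np.ndarray, min_area: int = 4) -> list[Detection]:
    """Extract 8-connected components of area ≥ ``min_area`` as detections.

    Output is sorted by area descending; ties broken by centroid (v, u)
    ascending.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    b = np.asarray(binary).astype(bool)
    labels, n = ndimage.label(b, structure=_EIGHT)
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(b, labels, idx).astype(int)
    objects = ndimage.find_objects(labels)
    dets: list[Detection] = []
    for lab, area in zip(idx, areas):
        if area < min_area:
            continue
        sl = objects[lab - 1]
        rows, cols = np.nonzero(labels[sl] == lab)
        v = rows.mean() + sl[0].start
        u = cols.mean() + sl[1].start
        bbox = (sl[1].start, sl[0].start, sl[1].stop - 1, sl[0].stop - 1)
        dets.append(Detection((float(u), float(v)), int(area), bbox))
    dets.sort(key=lambda d: (-d.area, d.centroid[1], d.centroid[0]))
    return dets


def detect_sequence(
    frames_by_camera: Sequence[Sequence[np.ndarray]],
    ranges: ColorRangeHSV | Sequence[ColorRangeHSV],
    masks: Sequence[np.ndarray | None] | None = None,
    kernel_size: int = 3,
    min_area: int = 4,
) -> list[DetectionSet]:
    """Run the detection chain over synchronized sequences, per color range.

    Each color range yields an independent :class:`DetectionSet` (separate
    marker colors — e.g. body vs head — are processed fully independently
    and only merged after triangulation).  Undistortion is *not* applied
    here; it happens at triangulation time.
    """
    if isinstance(ranges, ColorRangeHSV):
        ranges = [ranges]
    n_cam = len(frames_by_camera)
    counts = {j: len(frames_by_camera[j]) for j in range(n_cam)}
    if len(set(counts.values())) > 1:
        raise ValueError(
            "unsynchronized capture: frame counts differ across cameras "
            f"({counts})"
        )
    T = counts[0] if n_cam else 0
    if masks is None:
        masks = [None] * n_cam
    out = [DetectionSet(T, n_cam) for _ in ranges]
    for j in range(n_cam):
        for t in range(T):
            frame = frames_by_camera[j][t]
            for k, rng in enumerate(ranges):
                binary = threshold_hsv(frame, rng, masks[j])
                binary = clean_binary(binary, kernel_size)
                out[k].set(t, j, find_markers(binary, min_area))
    return out


def load_image_sequence(directory, pattern: str = "*.png") -> list[np.ndarray]:
    """Read a numbered frame directory (``cam00/frame_000000.png`` style)."""
    import imageio.v3 as iio

    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        paths = sorted(Path(directory).glob("*.tif*"))
    return [iio.imread(p)[..., :3] for p in paths]
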