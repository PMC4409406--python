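"""Marker detection: frames → 1-Hz centroid series.

Re-implements the image-processing stage of the arena workflow: each frame
carries a single bright marker blob over a noisy background; the detector
thresholds the frame at ``background mean + k·SD`` (background statistics
estimated per frame from the pixel population excluding the brightest 1 %,
which self-calibrates against lamp drift), keeps the largest connected
component above a minimum area, and reports its intensity-weighted
("centre of gravity") centroid in arena coordinates.

Coordinate convention: arena coordinates are centimetres, origin at the
bottom-left, y pointing up; image row 0 is the top of the frame, so the
vertical axis is inverted here and nowhere else.

The noise floor of a stationary marker (slight water movement, camera
vibration, sensor noise) is calibrated with :func:`estimate_noise_floor`,
which recommends the resting threshold used by the metrics stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .synthetic import FrameSequence

__all__ = [
    "Detection",
    "DetectionConfig",
    "NoiseFloor",
    "detect_marker",
    "track_sequence",
    "estimate_noise_floor",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholding and blob-selection parameters.

    ``px_per_cm`` may be left ``None`` when the frames themselves carry the
    scale (a :class:`~aquatrack.synthetic.FrameSequence` does); detection
    of a bare array without any scale is an error.
    """

    px_per_cm: float | None = None
    k_sigma: float = 5.0
    min_area_px: int = 4
    background_exclude_top: float = 0.01

    def __post_init__(self) -> None:
        if self.px_per_cm is not None and self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be at least 1")
        if not (0.0 <= self.background_exclude_top < 1.0):
            raise ValueError("background_exclude_top must lie in [0, 1)")


@dataclass
class Detection:
    """One frame's detection result in arena coordinates."""

    time_s: float
    x_cm: float
    y_cm: float
    present: bool
    blob_area_px: int


@dataclass
class NoiseFloor:
    """Stationary-marker calibration result.

    ``recommended_rest_threshold_cm`` is twice the largest per-axis
    frame-to-frame error, floored at 0.1 cm — the 1 mm margin that
    separates genuine relocation from apparent movement of a resting
    animal.
    """

    max_abs_dx_cm: float
    max_abs_dy_cm: float
    recommended_rest_threshold_cm: float

    def __post_init__(self) -> None:
        if self.recommended_rest_threshold_cm < max(
            self.max_abs_dx_cm, self.max_abs_dy_cm
        ):
            raise ValueError(
                "recommended threshold must cover the observed per-axis error"
            )


def detect_marker(
    frame: np.ndarray,
    cfg: DetectionConfig,
    *,
    px_per_cm: float | None = None,
    time_s: float = 0.0,
) -> Detection:
    """Detect the marker blob in a single grayscale frame.

    The frame is thresholded at background mean + ``k_sigma``·SD, the
    background statistics taken from all pixels at or below the 99th
    intensity percentile.  Among connected components of at least
    ``min_area_px`` pixels the largest is taken as the marker and its
    intensity-weighted centroid converted to cm.  ``present=False`` is
    returned when no component qualifies.
    """
    scale = px_per_cm if px_per_cm is not None else cfg.px_per_cm
    if scale is None:
        raise ValueError(
            "missing scale metadata: pass px_per_cm or set it in the config"
        )
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be a 2-D grayscale array")
    H = img.shape[0]

    cutoff = np.quantile(img, 1.0 - cfg.background_exclude_top)
    pool = img[img <= cutoff]
    bg_mean = float(pool.mean())
    bg_sd = float(pool.std())
    threshold = bg_mean + cfg.k_sigma * bg_sd

    mask = img > threshold
    absent = Detection(time_s, math.nan, math.nan, False, 0)
    if not mask.any():
        return absent
    labels = measure.label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())
    areas[0] = 0  # background label
    best = int(np.argmax(areas))
    if areas[best] < cfg.min_area_px:
        return absent
    rows, cols = np.nonzero(labels == best)
    w = img[rows, cols]
    wsum = float(w.sum())
    c_col = float((w * cols).sum() / wsum)
    c_row = float((w * rows).sum() / wsum)
    # pixel centre (row r, col c) sits at arena point
    # x = (c + 0.5)/scale,  y = (H - r - 0.5)/scale
    x_cm = (c_col + 0.5) / scale
    y_cm = (H - c_row - 0.5) / scale
    return Detection(time_s, x_cm, y_cm, True, int(areas[best]))


def track_sequence(frames, cfg: DetectionConfig | None = None) -> list[Detection]:
    """Run the detector over a time-ordered frame sequence.

    Accepts a :class:`~aquatrack.synthetic.FrameSequence` (whose scale
    metadata is used automatically) or any iterable of (time, frame)
    pairs.  Emits exactly one detection per frame — occluded frames come
    back as ``present=False``; no interpolation is performed.
    """
    if cfg is None:
        cfg = DetectionConfig()
    if isinstance(frames, FrameSequence):
        times = np.asarray(frames.time_s, dtype=float)
        imgs = frames.frames
        scale = frames.px_per_cm
    else:
        pairs = list(frames)
        if not pairs:
            return []
        times = np.array([float(t) for t, _ in pairs])
        imgs = [f for _, f in pairs]
        scale = cfg.px_per_cm
    if len(times) == 0:
        return []
    if len(times) > 1:
        gaps = np.diff(times)
        if np.any(np.abs(gaps - 1.0) > 1e-9):
            raise ValueError("frames must be uniformly spaced at 1 s")
    return [
        detect_marker(imgs[i], cfg, px_per_cm=scale, time_s=float(times[i]))
        for i in range(len(times))
    ]


def estimate_noise_floor(
    stationary, *, min_present: int = 60, floor_cm: float = 0.1
) -> NoiseFloor:
    """Calibrate the positional noise of a non-moving marker.

    ``stationary`` is the detection series of a marker known not to move
    (e.g. a paper chip recorded for 10 minutes).  The maximum absolute
    frame-to-frame displacement per axis over consecutive present frames
    is the measured error; the recommended resting threshold is twice the
    larger of the two, but never below ``floor_cm`` (1 mm), the margin
    that also covers small body movements of a live, resting animal.
    """
    xs, ys = [], []
    for d in stationary:
        if d.present:
            xs.append(d.x_cm)
            ys.append(d.y_cm)
    if len(xs) < min_present:
        raise ValueError(
            f"need at least {min_present} present detections, got {len(xs)}"
        )
    dx = np.abs(np.diff(xs))
    dy = np.abs(np.diff(ys))
    mx = float(dx.max())
    my = float(dy.max())
    return NoiseFloor(mx, my, max(floor_cm, 2.0 * max(mx, my)))
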