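"""Path segmentation and bookkeeping.

Detection series from the tracking stage (or trajectory tables loaded from
CSV) are cut into analysis-ready :class:`PathSegment` objects.  Three rules
shape the segmentation:

* points inside a margin zone along the arena walls are discarded, so that
  wall-following ("fence") behaviour does not bias the movement metrics;
* a detection gap (occluded marker) splits a path — unobserved intervals are
  never bridged by interpolation;
* downstream metrics only consider segments with a minimum number of
  locations (default 5), which keeps the scale-dependent metrics and the
  fractal regression on the same data basis.

Coordinates are in centimetres with the origin at the bottom-left corner of
the arena and y pointing up.  Sampling is uniform at the arena frame rate
(default 1 Hz); durations are derived from point counts, not wall-clock
stamps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ArenaConfig",
    "PathSegment",
    "PathSummary",
    "build_paths",
    "filter_min_locations",
    "summarize_paths",
]


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry and sampling of the observation arena.

    Defaults describe a 1 m² aquarium observed at one frame per second with
    a 10 cm exclusion margin along the walls.
    """

    width_cm: float = 100.0
    height_cm: float = 100.0
    margin_cm: float = 10.0
    frame_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValueError("width_cm and height_cm must be positive")
        if self.margin_cm < 0:
            raise ValueError("margin_cm must be non-negative")
        if self.margin_cm >= min(self.width_cm, self.height_cm) / 2:
            raise ValueError(
                "margin_cm must be smaller than half the arena's shorter side"
            )
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def dt_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    def is_interior(self, x_cm: float, y_cm: float) -> bool:
        """True if the point lies strictly outside the margin zone.

        A point exactly at distance ``margin_cm`` from a wall counts as
        *inside* the margin and is excluded.
        """
        m = self.margin_cm
        return (
            x_cm > m
            and x_cm < self.width_cm - m
            and y_cm > m
            and y_cm < self.height_cm - m
        )


@dataclass
class PathSegment:
    """A maximal uniformly sampled run of interior locations.

    ``time_s`` is strictly increasing with unit spacing ``1/frame_rate_hz``.
    """

    time_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    individual_id: str = "ind0"
    treatment: str = "none"
    segment_id: int = 0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        if not (len(self.time_s) == len(self.x_cm) == len(self.y_cm)):
            raise ValueError("time_s, x_cm and y_cm must have equal length")
        if len(self.time_s) == 0:
            raise ValueError("a PathSegment needs at least one point")
        if len(self.time_s) > 1 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def n_points(self) -> int:
        return len(self.time_s)

    @property
    def xy(self) -> np.ndarray:
        """Locations as an ``(n, 2)`` array."""
        return np.column_stack([self.x_cm, self.y_cm])

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass
class PathSummary:
    """Bookkeeping over a set of segments: counts, durations, coverage."""

    n_paths: int
    mean_duration_s: float  # NaN when there are no paths
    sd_duration_s: float  # NaN when there are fewer than two paths
    available_points_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.available_points_pct <= 100.0):
            raise ValueError("available_points_pct must be within [0, 100]")


def build_paths(
    detections,
    arena: ArenaConfig,
    *,
    individual_id: str = "ind0",
    treatment: str = "none",
) -> list[PathSegment]:
    """Cut a detection series into maximal interior runs.

    Parameters
    ----------
    detections
        Time-ordered sequence of objects with attributes ``time_s``,
        ``x_cm``, ``y_cm`` and ``present`` (the tracking stage's output), or
        a pandas DataFrame with those columns.
    arena
        Arena geometry; its margin and frame rate drive the splitting.

    Returns
    -------
    list of PathSegment
        One segment per maximal run of retained points that are consecutive
        in time (gap exactly one frame interval).  Absent detections and
        points within the margin zone are dropped and split runs.  Runs of a
        single point are kept here (they carry no steps and are removed by
        :func:`filter_min_locations` before any metric is computed), so the
        total number of retained points always equals the sum of segment
        sizes.
    """
    rows = _detection_rows(detections)
    dt = arena.dt_s
    tol = 1e-9 * max(1.0, dt)

    segments: list[PathSegment] = []
    cur_t: list[float] = []
    cur_x: list[float] = []
    cur_y: list[float] = []

    def flush() -> None:
        if cur_t:
            segments.append(
                PathSegment(
                    np.array(cur_t),
                    np.array(cur_x),
                    np.array(cur_y),
                    individual_id=individual_id,
                    treatment=treatment,
                    segment_id=len(segments),
                )
            )
            cur_t.clear()
            cur_x.clear()
            cur_y.clear()

    last_t = None
    for t, x, y, present in rows:
        if last_t is not None and t <= last_t:
            raise ValueError("detections must be strictly time-ordered")
        keep = bool(present) and arena.is_interior(x, y)
        if keep:
            if cur_t and abs(t - cur_t[-1] - dt) > tol:
                flush()  # gap: run of dropped frames in between
            cur_t.append(float(t))
            cur_x.append(float(x))
            cur_y.append(float(y))
        else:
            flush()
        last_t = t
    flush()
    return segments


def filter_min_locations(
    segments: Iterable[PathSegment], min_locations: int = 5
) -> list[PathSegment]:
    """Keep only segments with at least ``min_locations`` points.

    The same filter is applied before *all* metrics (step lengths, turning
    angles, resting times and the fractal regression) so that every metric
    summarises the same set of paths.
    """
    if min_locations < 2:
        raise ValueError("min_locations must be at least 2")
    return [s for s in segments if s.n_points >= min_locations]


def summarize_paths(
    segments: Sequence[PathSegment], total_recording_points: int
) -> PathSummary:
    """Coverage and duration bookkeeping for a set of segments.

    ``total_recording_points`` is the number of frames recorded (e.g. 3600
    for one hour at 1 Hz); the available-data percentage reports how many of
    them survived the margin/gap filtering.
    """
    if total_recording_points <= 0:
        raise ValueError("total_recording_points must be positive")
    retained = sum(s.n_points for s in segments)
    if retained > total_recording_points:
        raise ValueError(
            "retained points exceed total_recording_points"
        )
    n = len(segments)
    if n == 0:
        return PathSummary(0, math.nan, math.nan, 0.0)
    durations = np.array([(s.n_points - 1) * 1.0 for s in segments])
    mean_d = float(durations.mean())
    sd_d = float(durations.std(ddof=1)) if n > 1 else math.nan
    pct = 100.0 * retained / total_recording_points
    return PathSummary(n, mean_d, sd_d, pct)


def _detection_rows(detections):
    """Normalise detection input to an iterable of (t, x, y, present)."""
    try:  # pandas DataFrame
        cols = detections.columns
    except AttributeError:
        for d in detections:
            yield d.time_s, d.x_cm, d.y_cm, d.present
        return
    present = (
        detections["present"].to_numpy()
        if "present" in cols
        else np.ones(len(detections), dtype=bool)
    )
    x = detections["x_cm"].to_numpy(dtype=float, na_value=np.nan)
    y = detections["y_cm"].to_numpy(dtype=float, na_value=np.nan)
    t = detections["time_s"].to_numpy(dtype=float)
    ok = present & ~(np.isnan(x) | np.isnan(y))
    yield from zip(t, x, y, ok)
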