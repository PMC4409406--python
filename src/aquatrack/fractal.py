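"""Divider-method fractal dimension of movement paths.

The fractal dimension D is the scale-independent tortuosity index of a
trajectory: D = 1 for a straight line, D = 2 for Brownian motion that
eventually fills the plane.  It is measured with the classical divider
(ruler) method: the path is re-traced with a ruler of length δ, giving a
measured length L(δ); for a fractal path

    L(δ) = k · δ^(1 − D)

so D follows from the slope of an ordinary least-squares regression of
log L on log δ over a range of divider sizes.

Two details of the walk matter numerically and are fixed here:

* each divider step lands at the *exact* point along the polyline (linear
  interpolation within line segments) at straight-line (chord) distance δ
  from the current anchor — no snapping to vertices, which would bias L
  upward at large δ on coarsely sampled paths;
* the part of the path after the last full step is closed off by adding the
  straight distance from the last anchor to the final point, so that on a
  straight path L(δ) equals the true length exactly for every δ.

The mean estimator averages L over forward and backward traversals of the
path before the regression, and averages D over an individual's paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .trajectory import PathSegment

__all__ = [
    "DividerConfig",
    "FractalEstimate",
    "divider_length",
    "fractal_mean",
    "fractal_per_individual",
]

#: measured D below 1 - _D_NOISE_BOUND is flagged as suspect
_D_NOISE_BOUND = 0.05


@dataclass(frozen=True)
class DividerConfig:
    """Logarithmically spaced divider (ruler) sizes for the estimator.

    The defaults span half an isopod body length (0.25 cm) to a quarter of
    the 1-m observation scale; 200 sizes give a dense, stable regression.
    """

    delta_min_cm: float = 0.25
    delta_max_cm: float = 25.0
    n_dividers: int = 200

    def __post_init__(self) -> None:
        if not (0 < self.delta_min_cm < self.delta_max_cm):
            raise ValueError("need 0 < delta_min_cm < delta_max_cm")
        if self.n_dividers < 10:
            raise ValueError("n_dividers must be at least 10")

    def deltas(self) -> np.ndarray:
        return np.geomspace(self.delta_min_cm, self.delta_max_cm, self.n_dividers)


@dataclass
class FractalEstimate:
    """Result of the divider regression.

    ``D`` is the fractal dimension, ``k`` the length-scale intercept of the
    power law, ``r_squared`` the regression fit over the ``n_deltas_used``
    divider sizes that yielded a defined length.  ``suspect`` marks
    estimates below the estimator's noise bound (D < 0.95), which indicate
    a degenerate path or divider range rather than real geometry.
    """

    D: float
    k: float
    r_squared: float
    n_deltas_used: int
    config: DividerConfig

    @property
    def suspect(self) -> bool:
        return self.D < 1.0 - _D_NOISE_BOUND


def _as_xy(path) -> np.ndarray:
    if isinstance(path, PathSegment):
        return path.xy
    xy = np.asarray(path, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("path must be a PathSegment or an (n, 2) array")
    return xy


def divider_length(path, delta_cm: float) -> tuple[float, int]:
    """Measure a polyline with a ruler of length ``delta_cm``.

    Starting from the first point, the walk repeatedly advances to the
    first point along the polyline at chord distance δ from the current
    anchor.  The measured length is (number of full steps)·δ plus the
    straight-line remainder from the last anchor to the final point.

    Returns
    -------
    (L, n_steps)
        Measured length in cm and the number of full divider steps.

    Raises
    ------
    ValueError
        If δ is not positive, or the path is shorter than δ (no full step
        fits, so L(δ) is undefined).
    """
    if delta_cm <= 0:
        raise ValueError("delta_cm must be positive")
    xy = _as_xy(path)
    if len(xy) < 2:
        raise ValueError("path needs at least 2 points")
    L, steps = _divider_walk(xy, float(delta_cm))
    if steps == 0:
        raise ValueError(
            f"path is shorter than the divider: no step of {delta_cm} cm fits"
        )
    return L, steps


def _divider_walk(xy: np.ndarray, delta: float) -> tuple[float, int]:
    """Core divider walk; returns (L, n_full_steps), steps may be 0."""
    n = len(xy)
    seg = np.diff(xy, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arc = np.concatenate([[0.0], np.cumsum(seglen)])

    ax, ay = float(xy[0, 0]), float(xy[0, 1])  # current anchor
    arc_here = 0.0
    i = 0  # anchor lies on segment i at fraction t
    t = 0.0
    steps = 0
    X = xy[:, 0]
    Y = xy[:, 1]

    while True:
        # chord distance cannot exceed arc distance: every vertex with
        # arc < arc_here + delta is strictly within the ruler, so the scan
        # may start at the first vertex at arc distance >= delta.
        j0 = int(np.searchsorted(arc, arc_here + delta))
        if j0 >= n:
            break
        j1 = -1
        j = j0
        while j < n:
            jend = min(n, j + 512)
            d2 = (X[j:jend] - ax) ** 2 + (Y[j:jend] - ay) ** 2
            hit = np.nonzero(d2 >= delta * delta)[0]
            if hit.size:
                j1 = j + int(hit[0])
                break
            j = jend
        if j1 < 0:
            break
        # first crossing lies on segment (j1-1, j1): distance to the anchor
        # is convex along a straight segment, and all vertices before j1
        # are within delta, so the segment interior crosses exactly once.
        k = j1 - 1
        qx, qy = float(X[k]), float(Y[k])
        ux, uy = float(X[j1]) - qx, float(Y[j1]) - qy
        wx, wy = qx - ax, qy - ay
        a = ux * ux + uy * uy
        b = wx * ux + wy * uy
        c = wx * wx + wy * wy - delta * delta
        disc = b * b - a * c
        if disc < 0.0:  # numerical guard; crossing at the far vertex
            s = 1.0
        else:
            s = (-b + math.sqrt(disc)) / a
            s = min(max(s, 0.0), 1.0)
        if k == i and s <= t:  # guard against stalling on the anchor segment
            s = math.nextafter(t, 1.0)
        ax, ay = qx + s * ux, qy + s * uy
        i, t = k, s
        arc_here = float(arc[k]) + s * float(seglen[k]) if seglen[k] > 0 else float(arc[k])
        steps += 1

    remainder = math.hypot(float(X[-1]) - ax, float(Y[-1]) - ay)
    return steps * delta + remainder, steps


def fractal_mean(
    path,
    config: DividerConfig | None = None,
    *,
    min_locations: int = 5,
    min_deltas: int = 10,
) -> FractalEstimate:
    """Divider-method D for one path, averaging both traversal directions.

    For every divider size the path is measured forward and backward and
    the two lengths averaged; divider sizes for which no full step fits in
    either direction are dropped from the regression.  D = 1 − slope of
    the OLS fit of log L on log δ.

    Raises
    ------
    ValueError
        If the path has fewer than ``min_locations`` points (too short for
        a robust regression) or fewer than ``min_deltas`` divider sizes
        yield a defined length.
    """
    if config is None:
        config = DividerConfig()
    xy = _as_xy(path)
    if len(xy) < min_locations:
        raise ValueError(
            f"path has {len(xy)} locations; at least {min_locations} required"
        )
    xy_rev = xy[::-1]
    deltas = config.deltas()
    used_d: list[float] = []
    used_L: list[float] = []
    for delta in deltas:
        Lf, sf = _divider_walk(xy, float(delta))
        Lb, sb = _divider_walk(xy_rev, float(delta))
        if sf == 0 or sb == 0:
            continue
        used_d.append(float(delta))
        used_L.append(0.5 * (Lf + Lb))
    if len(used_d) < min_deltas:
        raise ValueError(
            f"only {len(used_d)} divider sizes yielded a defined length "
            f"(minimum {min_deltas}); widen the divider range or use a longer path"
        )
    logd = np.log(used_d)
    logL = np.log(used_L)
    if np.allclose(logL, logL[0]):
        # perfectly straight path: constant L, zero slope by definition
        slope, intercept, r2 = 0.0, float(logL[0]), 1.0
    else:
        res = stats.linregress(logd, logL)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
    return FractalEstimate(
        D=1.0 - slope,
        k=float(np.exp(intercept)),
        r_squared=r2,
        n_deltas_used=len(used_d),
        config=config,
    )


def fractal_per_individual(
    segments: Iterable[PathSegment],
    config: DividerConfig | None = None,
    *,
    min_locations: int = 5,
) -> float:
    """Mean D over one individual's eligible paths.

    Paths with fewer than ``min_locations`` points are skipped; when an
    individual yielded several paths the per-path estimates are averaged
    with equal weight.
    """
    Ds = []
    for seg in segments:
        if seg.n_points < min_locations:
            continue
        try:
            Ds.append(fractal_mean(seg, config, min_locations=min_locations).D)
        except ValueError:
            continue  # too short for the divider range
    if not Ds:
        raise ValueError("no eligible segment for this individual")
    return float(np.mean(Ds))
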