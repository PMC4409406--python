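"""Circular statistics for turning angles.

Turning angles live on the circle: 180° and −180° are the same direction
(straight backwards), so linear summaries are meaningless and all
descriptive statistics and tests here respect the topology.  The module
provides the standard trigonometric-moment summary (circular mean, mean
resultant length R̄, circular SD, von Mises concentration κ), the
Watson–Wheeler rank test for homogeneity of two or more angular samples,
and circular boxplot statistics (median, hinges, fences, outliers) for
summarising pooled turning-angle distributions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .results import ComparisonResult

__all__ = [
    "CircularSample",
    "CircularSummary",
    "CircularBoxplotStats",
    "circular_summary",
    "watson_wheeler",
    "circular_boxplot_stats",
]


def wrap_deg(a) -> np.ndarray:
    """Map angles into (−180, 180]."""
    a = np.asarray(a, dtype=float)
    w = np.mod(a + 180.0, 360.0) - 180.0
    return np.where(w == -180.0, 180.0, w)


@dataclass
class CircularSample:
    angles_deg: np.ndarray
    group_label: str = ""

    def __post_init__(self) -> None:
        self.angles_deg = wrap_deg(self.angles_deg)
        if len(self.angles_deg) < 1:
            raise ValueError("a CircularSample needs at least one angle")


@dataclass
class CircularSummary:
    """Trigonometric-moment summary of an angular sample.

    ``sd_deg`` is the circular standard deviation sqrt(−2 ln R̄); ``kappa``
    the von Mises concentration recovered from R̄; ``sd_arithmetic_deg``
    the plain linear SD of the wrapped angles, exported alongside because
    summary tables in the field sometimes print it instead.
    """

    mean_deg: float
    sd_deg: float
    R_bar: float
    kappa: float
    n: int
    sd_arithmetic_deg: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.R_bar <= 1.0 + 1e-12):
            raise ValueError("R_bar must lie in [0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")


@dataclass
class CircularBoxplotStats:
    median_deg: float
    hinge_low_deg: float
    hinge_high_deg: float
    fence_low_deg: float
    fence_high_deg: float
    outliers_deg: np.ndarray
    iqr_deg: float


def _kappa_from_rbar(r: float) -> float:
    """Invert the Bessel-function ratio A(κ) = R̄ with the standard
    piecewise rational approximation (Fisher 1993)."""
    if r < 1e-12:
        return 0.0
    if r < 0.53:
        return 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    denom = r**3 - 4.0 * r**2 + 3.0 * r
    return 1.0 / denom if denom > 0 else math.inf


def circular_summary(sample) -> CircularSummary:
    """Circular mean, concentration and spread of an angular sample.

    When the resultant vanishes (e.g. an exactly antipodal pair) the mean
    direction is undefined: R̄ ≈ 0 is returned with ``mean_deg = NaN`` and
    a warning is emitted.
    """
    angles = _angles_of(sample)
    n = len(angles)
    if n < 2:
        raise ValueError("circular_summary needs at least 2 angles")
    rad = np.radians(angles)
    C = float(np.mean(np.cos(rad)))
    S = float(np.mean(np.sin(rad)))
    R = math.hypot(C, S)
    if R < 1e-9:
        warnings.warn(
            "mean resultant length is ~0; mean direction undefined",
            stacklevel=2,
        )
        mean = math.nan
        sd = math.inf
    else:
        mean = float(wrap_deg(math.degrees(math.atan2(S, C))))
        sd = math.degrees(math.sqrt(max(0.0, -2.0 * math.log(min(R, 1.0)))))
    return CircularSummary(
        mean_deg=mean,
        sd_deg=sd,
        R_bar=min(R, 1.0),
        kappa=_kappa_from_rbar(R),
        n=n,
        sd_arithmetic_deg=float(np.std(angles, ddof=1)),
    )


def watson_wheeler(samples, *, min_n_warn: int = 10) -> ComparisonResult:
    """Watson–Wheeler (Mardia) test of homogeneity for k ≥ 2 angular samples.

    The pooled angles are ranked around the circle and mapped to uniform
    scores β_j = 2π·rank/N; with per-group resultant components
    C_i = Σ cos β, S_i = Σ sin β the statistic is

        W = 2 Σ_i (C_i² + S_i²) / n_i,

    compared against chi-square with 2(k−1) degrees of freedom.  Exact ties
    are broken by adding deterministic uniform jitter far below angular
    measurement resolution (< 1e-6°), as circular ranks require distinct
    values.

    ``samples`` may be a mapping of label → angle array, or a sequence of
    :class:`CircularSample` / arrays.
    """
    groups = _as_groups(samples)
    k = len(groups)
    if k < 2:
        raise ValueError("watson_wheeler needs at least 2 groups")
    sizes = {label: len(a) for label, a in groups}
    for label, n_i in sizes.items():
        if n_i < 2:
            raise ValueError(f"group {label!r} has fewer than 2 angles")
        if n_i < min_n_warn:
            warnings.warn(
                f"group {label!r} has n={n_i} < {min_n_warn}; "
                "chi-square approximation may be poor",
                stacklevel=2,
            )
    pooled = np.concatenate([a for _, a in groups])
    labels = np.concatenate(
        [np.full(len(a), i) for i, (_, a) in enumerate(groups)]
    )
    pooled = wrap_deg(pooled)
    if len(np.unique(pooled)) < len(pooled):
        jitter_rng = np.random.default_rng(181372)  # fixed: determinism
        pooled = pooled + jitter_rng.uniform(-5e-7, 5e-7, size=len(pooled))
    N = len(pooled)
    ranks = stats.rankdata(pooled, method="ordinal")
    beta = 2.0 * math.pi * ranks / N
    W = 0.0
    for i in range(k):
        sel = labels == i
        C = float(np.sum(np.cos(beta[sel])))
        S = float(np.sum(np.sin(beta[sel])))
        W += (C * C + S * S) / np.count_nonzero(sel)
    W *= 2.0
    df = 2 * (k - 1)
    p = float(stats.chi2.sf(W, df))
    return ComparisonResult(
        metric="turning_angle",
        test="watson_wheeler",
        statistic=float(W),
        df=df,
        p_value=p,
        n_per_group=sizes,
    )


def circular_boxplot_stats(sample, *, whisker: float = 1.5) -> CircularBoxplotStats:
    """Circular boxplot summary: median, hinges, fences and outliers.

    The circular median minimises the mean arc distance to the sample;
    hinges are the quartiles of the *signed arc deviations* from the median
    (in (−180, 180]); fences sit ``whisker`` × IQR beyond the hinges, and
    points past them are reported as outliers.  All outputs are absolute
    angles in degrees, equivariant under common rotation of the sample.
    """
    angles = _angles_of(sample)
    n = len(angles)
    if n < 5:
        raise ValueError("circular_boxplot_stats needs at least 5 angles")
    summ_R = _rbar(angles)
    if summ_R < 1e-9:
        raise ValueError("mean resultant length ~0: circular median unstable")
    if summ_R < 0.2:
        warnings.warn(
            "weakly concentrated sample (R_bar < 0.2); "
            "circular boxplot may be unstable",
            stacklevel=2,
        )
    median = _circular_median(angles)
    dev = wrap_deg(angles - median)
    q1, q3 = np.percentile(dev, [25.0, 75.0])
    iqr = float(q3 - q1)
    f_lo = q1 - whisker * iqr
    f_hi = q3 + whisker * iqr
    out = angles[(dev < f_lo) | (dev > f_hi)]
    return CircularBoxplotStats(
        median_deg=median,
        hinge_low_deg=float(wrap_deg(median + q1)),
        hinge_high_deg=float(wrap_deg(median + q3)),
        fence_low_deg=float(wrap_deg(median + f_lo)),
        fence_high_deg=float(wrap_deg(median + f_hi)),
        outliers_deg=np.sort(out),
        iqr_deg=iqr,
    )


def _circular_median(angles: np.ndarray) -> float:
    """Data-point candidate minimising the mean absolute arc deviation.

    Each candidate's total arc distance is evaluated in O(log n) from
    prefix sums over the sorted, period-extended sample, so the whole
    search is O(n log n); ties go to the first candidate in sorted order.
    """
    t = np.sort(angles)
    n = len(t)
    ext = np.concatenate([t, t + 360.0])
    P = np.concatenate([[0.0], np.cumsum(ext)])
    m = t  # candidates
    lo = np.searchsorted(ext, m - 180.0, side="left")
    mid = np.searchsorted(ext, m, side="right")
    hi = lo + n
    mid = np.clip(mid, lo, hi)
    below = m * (mid - lo) - (P[mid] - P[lo])
    above = (P[hi] - P[mid]) - m * (hi - mid)
    total = below + above
    return float(t[int(np.argmin(total))])


def _angles_of(sample) -> np.ndarray:
    if isinstance(sample, CircularSample):
        return sample.angles_deg
    a = wrap_deg(np.asarray(sample, dtype=float))
    if a.ndim != 1:
        raise ValueError("angles must be a 1-D array")
    return a


def _rbar(angles_deg: np.ndarray) -> float:
    rad = np.radians(angles_deg)
    return math.hypot(float(np.mean(np.cos(rad))), float(np.mean(np.sin(rad))))


def _as_groups(samples) -> list[tuple[str, np.ndarray]]:
    if hasattr(samples, "items"):
        return [(str(k), _angles_of(v)) for k, v in samples.items()]
    out = []
    for i, s in enumerate(samples):
        if isinstance(s, CircularSample):
            out.append((s.group_label or f"group{i}", s.angles_deg))
        else:
            out.append((f"group{i}", _angles_of(s)))
    return out
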