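"""Per-segment movement metrics.

Everything here operates on a :class:`~aquatrack.trajectory.PathSegment`
sampled at 1 Hz.  The central convention is the relocation threshold
(default 0.1 cm): a 1-second step smaller than 1 mm is indistinguishable
from positional noise and small body movements of a stationary animal
(breathing, leg motion), so such intervals count as *resting* and larger
steps as *relocation*.  A step exactly at the threshold counts as
relocation.  Turning angles are only defined between relocation steps that
are adjacent in time — a resting interval breaks the chain, because the
animal's heading during rest is unobservable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trajectory import PathSegment

__all__ = [
    "REST_THRESHOLD_CM",
    "StepSeries",
    "TurnSeries",
    "RestingResult",
    "StepDistributionFit",
    "step_lengths",
    "resting_fraction",
    "turning_angles",
    "stops_per_distance",
    "fit_step_distribution",
]

#: default relocation/resting displacement threshold (1 mm)
REST_THRESHOLD_CM = 0.1


@dataclass
class StepSeries:
    """Step lengths D_i per 1-s interval with their relocation flags."""

    step_cm: np.ndarray
    is_relocation: np.ndarray
    threshold_cm: float = REST_THRESHOLD_CM

    def __len__(self) -> int:
        return len(self.step_cm)

    @property
    def relocation_steps(self) -> np.ndarray:
        return self.step_cm[self.is_relocation]

    @property
    def total_distance_cm(self) -> float:
        """Distance travelled, summing relocation steps only (sub-threshold
        displacements are positional noise, not locomotion)."""
        return float(self.relocation_steps.sum())


@dataclass
class TurnSeries:
    """Signed turning angles in degrees, in (−180, 180], counterclockwise
    positive; 0° is straight ahead."""

    theta_deg: np.ndarray

    def __len__(self) -> int:
        return len(self.theta_deg)


@dataclass
class RestingResult:
    resting_fraction: float
    threshold_cm: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.resting_fraction <= 1.0):
            raise ValueError("resting_fraction must lie in [0, 1]")


@dataclass
class StepDistributionFit:
    """Exponential-vs-power-law verdict on relocation step lengths.

    Both candidates are fitted by maximum likelihood above a common lower
    cutoff ``x_min_cm``: a shifted exponential (rate ``rate_per_cm``) and a
    Pareto power law (exponent ``mu``).  The verdict follows the Akaike
    information criterion: a model wins when its AIC undercuts the other's
    by more than ``delta_aic_rule``; smaller margins, or fewer than the
    minimum number of steps, are ``inconclusive``.
    """

    verdict: str  # "exponential" | "powerlaw" | "inconclusive"
    n_steps: int
    x_min_cm: float
    loglik_exponential: float
    loglik_powerlaw: float
    aic_exponential: float
    aic_powerlaw: float
    rate_per_cm: float
    mu: float
    delta_aic_rule: float = 2.0


def step_lengths(
    segment: PathSegment, threshold_cm: float = REST_THRESHOLD_CM
) -> StepSeries:
    """Euclidean distance between consecutive locations, with relocation
    flags (``step >= threshold``).

    Raises ``ValueError`` for segments of fewer than 2 points.
    """
    if segment.n_points < 2:
        raise ValueError("step lengths need at least 2 points")
    d = np.diff(segment.xy, axis=0)
    steps = np.hypot(d[:, 0], d[:, 1])
    return StepSeries(steps, steps >= threshold_cm, threshold_cm)


def resting_fraction(
    steps: StepSeries, threshold_cm: float | None = None
) -> RestingResult:
    """Fraction of 1-s intervals spent resting (step below the threshold).

    Passing ``threshold_cm`` reclassifies the series; by default the
    series' own threshold is used.  Resting and moving fractions sum to 1.
    """
    if len(steps) == 0:
        raise ValueError("empty step series")
    thr = steps.threshold_cm if threshold_cm is None else threshold_cm
    resting = np.count_nonzero(steps.step_cm < thr)
    return RestingResult(resting / len(steps), thr)


def turning_angles(
    segment: PathSegment, threshold_cm: float = REST_THRESHOLD_CM
) -> TurnSeries:
    """Signed angle between successive relocation steps adjacent in time.

    The angle is the deviation from straight-line locomotion: for step
    vectors v_i, v_{i+1} (both relocations, no rest in between) it is
    atan2(v_i × v_{i+1}, v_i · v_{i+1}) in degrees, mapped into
    (−180, 180] with a full reversal reported as +180°.
    """
    if segment.n_points < 3:
        raise ValueError("turning angles need at least 3 points")
    v = np.diff(segment.xy, axis=0)
    norm = np.hypot(v[:, 0], v[:, 1])
    reloc = norm >= threshold_cm
    pair = reloc[:-1] & reloc[1:]
    a = v[:-1][pair]
    b = v[1:][pair]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]
    theta = np.degrees(np.arctan2(cross, dot))
    theta[theta <= -180.0] += 360.0
    return TurnSeries(theta)


def stops_per_distance(steps: StepSeries) -> float:
    """Move→rest transitions per metre of distance travelled.

    A *stop* is a relocation interval immediately followed by a resting
    interval.  The rate divides the stop count by the total relocation
    distance, reported per metre.
    """
    dist_cm = steps.total_distance_cm
    if dist_cm <= 0:
        raise ValueError("total relocation distance is zero; rate undefined")
    r = steps.is_relocation
    n_stops = int(np.count_nonzero(r[:-1] & ~r[1:]))
    return n_stops / (dist_cm / 100.0)


def fit_step_distribution(
    steps,
    x_min_cm: float = REST_THRESHOLD_CM,
    *,
    min_steps: int = 50,
    delta_aic: float = 2.0,
) -> StepDistributionFit:
    """Classify relocation step lengths as exponential or power-law.

    Accepts a :class:`StepSeries` (its relocation steps are used) or a
    plain array of step lengths; values below ``x_min_cm`` are discarded
    before fitting, since below the relocation threshold the data are
    noise by calibration.

    The shifted-exponential MLE is ``rate = 1 / (mean(x) − x_min)`` and the
    Pareto MLE is ``mu = 1 + n / Σ log(x / x_min)``; both models have one
    free parameter, so the AIC comparison reduces to the likelihood ratio.
    """
    if isinstance(steps, StepSeries):
        x = steps.relocation_steps
    else:
        x = np.asarray(steps, dtype=float)
    x = x[x >= x_min_cm]
    n = len(x)
    if n == 0:
        raise ValueError("no steps at or above x_min_cm; nothing to fit")
    if x_min_cm <= 0:
        raise ValueError("x_min_cm must be positive")

    mean_excess = float(x.mean() - x_min_cm)
    sum_log = float(np.sum(np.log(x / x_min_cm)))
    # degenerate samples (all steps at x_min) admit no finite MLE
    if mean_excess <= 0 or sum_log <= 0:
        rate = math.inf
        mu = math.inf
        ll_exp = ll_pow = math.inf
        aic_exp = aic_pow = -math.inf
        verdict = "inconclusive"
    else:
        rate = 1.0 / mean_excess
        mu = 1.0 + n / sum_log
        ll_exp = n * math.log(rate) - rate * (mean_excess * n)
        ll_pow = n * math.log(mu - 1.0) - n * math.log(x_min_cm) - mu * sum_log
        aic_exp = 2.0 - 2.0 * ll_exp
        aic_pow = 2.0 - 2.0 * ll_pow
        if n < min_steps:
            verdict = "inconclusive"
        elif aic_exp + delta_aic < aic_pow:
            verdict = "exponential"
        elif aic_pow + delta_aic < aic_exp:
            verdict = "powerlaw"
        else:
            verdict = "inconclusive"
    return StepDistributionFit(
        verdict=verdict,
        n_steps=n,
        x_min_cm=x_min_cm,
        loglik_exponential=ll_exp,
        loglik_powerlaw=ll_pow,
        aic_exponential=aic_exp,
        aic_powerlaw=aic_pow,
        rate_per_cm=rate,
        mu=mu,
        delta_aic_rule=delta_aic,
    )
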