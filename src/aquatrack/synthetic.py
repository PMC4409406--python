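"""Synthetic trajectories and rendered frame sequences.

The generators in this module produce data with the statistical structure
the analysis pipeline assumes, so that every downstream stage — marker
detection, path filtering, movement metrics, fractal and circular
statistics — can be exercised and calibrated without recorded video.

The walker is a two-state (move/rest) correlated random walk sampled at
1 Hz, mirroring a single marked macroinvertebrate in a 1 m² arena:

* per-second move↔rest transitions form a first-order Markov chain, so
  bout lengths are geometric and the stationary resting occupancy is
  ``p_move_to_rest / (p_move_to_rest + p_rest_to_move)``;
* moving steps draw their length from either an exponential distribution
  (rate per cm) or a Pareto power law (exponent mu, lower cutoff x_min) —
  the two step-length regimes that arena experiments distinguish;
* headings turn by von Mises angles concentrated on 0° (straight ahead)
  with concentration kappa; the heading persists unchanged through rest
  bouts, since reorientation during rest is unobservable at 1 Hz;
* walls reflect specularly (the mirror fold of the unbounded walk);
* observed positions carry Gaussian jitter emulating the positional noise
  of centroid tracking, so that during rest the measured displacement is
  jitter only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .trajectory import ArenaConfig

__all__ = [
    "ExponentialSteps",
    "PowerLawSteps",
    "CRWParams",
    "SceneConfig",
    "Trajectory",
    "FrameSequence",
    "generate_crw",
    "generate_brownian",
    "generate_reference_path",
    "render_frames",
    "generate_density_experiment",
    "rest_occupancy_params",
]


@dataclass(frozen=True)
class ExponentialSteps:
    """Exponential moving-step lengths with the given rate (per cm)."""

    rate_per_cm: float = 1.4

    def __post_init__(self) -> None:
        if self.rate_per_cm <= 0:
            raise ValueError("step_model.rate_per_cm must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.exponential(1.0 / self.rate_per_cm, n)

    @property
    def mean_cm(self) -> float:
        return 1.0 / self.rate_per_cm


@dataclass(frozen=True)
class PowerLawSteps:
    """Pareto moving-step lengths: pdf ∝ x^(−mu) above a hard cutoff x_min."""

    mu: float = 2.0
    x_min_cm: float = 0.1

    def __post_init__(self) -> None:
        if self.mu <= 1:
            raise ValueError("step_model.mu must exceed 1")
        if self.x_min_cm <= 0:
            raise ValueError("step_model.x_min_cm must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.x_min_cm * (1.0 + rng.pareto(self.mu - 1.0, n))


StepModel = Union[ExponentialSteps, PowerLawSteps]


@dataclass(frozen=True)
class CRWParams:
    """Generative parameters of the two-state correlated random walker.

    ``n_steps`` counts 1-second intervals (one hour of recording at 1 Hz is
    3600).  ``jitter_sd_cm`` defaults to 0.02 cm so the stationary noise
    floor stays below the 0.05 cm detection granularity of the tracking
    stage.
    """

    n_steps: int = 3600
    p_move_to_rest: float = 0.1
    p_rest_to_move: float = 0.2
    step_model: StepModel = ExponentialSteps()
    turn_kappa: float = 5.0
    jitter_sd_cm: float = 0.02
    start_xy_cm: tuple[float, float] = (50.0, 50.0)
    arena: ArenaConfig = field(default_factory=ArenaConfig)

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")
        for name in ("p_move_to_rest", "p_rest_to_move"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.turn_kappa < 0:
            raise ValueError("turn_kappa must be non-negative")
        if self.jitter_sd_cm < 0:
            raise ValueError("jitter_sd_cm must be non-negative")
        x0, y0 = self.start_xy_cm
        if not (0 <= x0 <= self.arena.width_cm and 0 <= y0 <= self.arena.height_cm):
            raise ValueError("start_xy_cm must lie inside the arena")

    @property
    def stationary_rest_occupancy(self) -> float:
        """Long-run fraction of intervals spent resting."""
        p, q = self.p_move_to_rest, self.p_rest_to_move
        if p == 0:
            return 0.0
        if q == 0:
            return 1.0
        return p / (p + q)


@dataclass(frozen=True)
class SceneConfig:
    """Rendering model for synthetic frames: one bright Gaussian marker blob
    over noisy background, with intermittent marker invisibility."""

    arena: ArenaConfig = field(default_factory=ArenaConfig)
    px_per_cm: float = 5.0
    blob_sigma_px: float = 2.0
    blob_peak: float = 200.0
    background_mean: float = 30.0
    background_sd: float = 5.0
    occlusion_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        if self.blob_sigma_px <= 0:
            raise ValueError("blob_sigma_px must be positive")
        if self.blob_peak <= self.background_mean:
            raise ValueError("blob_peak must exceed background_mean")
        if self.background_sd < 0:
            raise ValueError("background_sd must be non-negative")
        if not (0.0 <= self.occlusion_prob <= 1.0):
            raise ValueError("occlusion_prob must lie in [0, 1]")

    @property
    def shape_px(self) -> tuple[int, int]:
        return (
            int(round(self.arena.height_cm * self.px_per_cm)),
            int(round(self.arena.width_cm * self.px_per_cm)),
        )


@dataclass
class Trajectory:
    """A 1-Hz coordinate series, optionally with the generator's true
    move/rest state per interval (``moving[i]`` covers t=i → t=i+1)."""

    time_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    moving: np.ndarray | None = None
    individual_id: str = "ind0"
    treatment: str = "none"

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x_cm, self.y_cm])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "x_cm": self.x_cm,
                "y_cm": self.y_cm,
                "individual_id": self.individual_id,
                "treatment": self.treatment,
            }
        )


@dataclass
class FrameSequence:
    """8-bit grayscale frames with the scale metadata detection needs."""

    frames: np.ndarray  # (n, H, W) uint8
    time_s: np.ndarray
    px_per_cm: float
    arena: ArenaConfig
    occluded: np.ndarray  # ground truth, (n,) bool

    def __len__(self) -> int:
        return len(self.frames)


def _fold(v: np.ndarray, width: float) -> np.ndarray:
    """Map an unbounded coordinate onto [0, width] by specular reflection."""
    r = np.mod(v, 2.0 * width)
    return width - np.abs(r - width)


def _markov_states(
    rng: np.random.Generator, n: int, p_mr: float, p_rm: float
) -> np.ndarray:
    """Move(True)/rest(False) state per interval; starts in the move state.

    Sojourn times of a first-order chain are geometric, so the sequence is
    built from alternating geometric bout lengths, which is exact and fast.
    """
    if p_mr == 0.0:
        return np.ones(n, dtype=bool)
    if p_rm == 0.0:
        # absorbing rest: one initial move bout, then rest forever
        moving = np.zeros(n, dtype=bool)
        moving[: min(int(rng.geometric(p_mr)), n)] = True
        return moving
    cycle = 1.0 / p_mr + 1.0 / p_rm
    k = max(8, int(2.0 * n / cycle) + 8)
    while True:
        move_bouts = rng.geometric(p_mr, size=k)
        rest_bouts = rng.geometric(p_rm, size=k)
        sizes = np.ravel(np.column_stack([move_bouts, rest_bouts]))
        if sizes.sum() >= n:
            break
        k *= 2
    states = np.repeat(np.tile([True, False], k), sizes)
    return states[:n]


def _resolve_seed(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_crw(params: CRWParams, seed) -> Trajectory:
    """Simulate the two-state correlated random walk.

    The same ``(params, seed)`` pair always reproduces the identical
    trajectory.  Returned positions are the observed (jittered) ones; the
    generator's true interval states are attached as ``moving`` for
    calibration tests.
    """
    if not isinstance(params, CRWParams):
        raise TypeError("params must be a CRWParams")
    rng = _resolve_seed(seed)
    n = params.n_steps

    heading0 = rng.uniform(-math.pi, math.pi)
    moving = _markov_states(rng, n, params.p_move_to_rest, params.p_rest_to_move)
    turns = rng.vonmises(0.0, params.turn_kappa, n)
    lengths = params.step_model.sample(rng, n)

    # heading only advances on moving intervals; rests leave it unchanged
    heading = heading0 + np.cumsum(np.where(moving, turns, 0.0))
    dx = np.where(moving, lengths * np.cos(heading), 0.0)
    dy = np.where(moving, lengths * np.sin(heading), 0.0)

    x = params.start_xy_cm[0] + np.concatenate([[0.0], np.cumsum(dx)])
    y = params.start_xy_cm[1] + np.concatenate([[0.0], np.cumsum(dy)])
    x = _fold(x, params.arena.width_cm)
    y = _fold(y, params.arena.height_cm)

    if params.jitter_sd_cm > 0:
        jit = rng.normal(0.0, params.jitter_sd_cm, size=(n + 1, 2))
        x = x + jit[:, 0]
        y = y + jit[:, 1]

    return Trajectory(
        time_s=np.arange(n + 1, dtype=float),
        x_cm=x,
        y_cm=y,
        moving=moving,
    )


def generate_brownian(n_steps: int, step_sd_cm: float, seed) -> Trajectory:
    """Unbounded isotropic Gaussian random walk at unit time spacing.

    Mean squared displacement after k steps is ``k * 2 * step_sd_cm**2``
    (two independent axes), the planar diffusion law; with dense sampling
    its divider-method dimension approaches 2.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    if step_sd_cm < 0:
        raise ValueError("step_sd_cm must be non-negative")
    rng = _resolve_seed(seed)
    inc = rng.normal(0.0, step_sd_cm, size=(n_steps, 2))
    pos = np.vstack([[0.0, 0.0], np.cumsum(inc, axis=0)])
    return Trajectory(
        time_s=np.arange(n_steps + 1, dtype=float),
        x_cm=pos[:, 0],
        y_cm=pos[:, 1],
    )


def generate_reference_path(
    kind: str, extent_cm: float, *, n_points: int = 101, level: int = 1
) -> Trajectory:
    """Deterministic reference paths with known fractal dimension.

    ``straight`` gives ``n_points`` collinear equally spaced points over
    ``extent_cm`` (D = 1).  ``koch`` gives the triadic Koch polyline at the
    given construction level, baseline scaled to ``extent_cm``; its total
    length is ``extent_cm * (4/3)**level`` and its dimension in the
    self-similar range is log 4 / log 3 ≈ 1.2619.
    """
    if extent_cm <= 0:
        raise ValueError("extent_cm must be positive")
    if kind == "straight":
        if n_points < 2:
            raise ValueError("n_points must be at least 2")
        x = np.linspace(0.0, extent_cm, n_points)
        y = np.zeros(n_points)
    elif kind == "koch":
        if not (0 <= level <= 6):
            raise ValueError("koch level must be between 0 and 6")
        pts = np.array([0.0 + 0.0j, extent_cm + 0.0j])
        rot = np.exp(1j * math.pi / 3.0)
        for _ in range(level):
            a = pts[:-1]
            d = np.diff(pts) / 3.0
            pts = np.column_stack(
                [a, a + d, a + d + d * rot, a + 2 * d]
            ).ravel()
            pts = np.append(pts, a[-1] + 3 * d[-1])
        x = pts.real.copy()
        y = pts.imag.copy()
    else:
        raise ValueError(f"unsupported reference path kind: {kind!r}")
    return Trajectory(time_s=np.arange(len(x), dtype=float), x_cm=x, y_cm=y)


def render_frames(traj: Trajectory, scene: SceneConfig, seed) -> FrameSequence:
    """Render one 8-bit grayscale frame per trajectory point.

    The marker is a 2-D Gaussian of width ``blob_sigma_px`` at the true
    position unless the frame is occluded; background pixels are i.i.d.
    Gaussian noise around ``background_mean``.  Pixel row 0 is the top of
    the image; arena y points up (the detection stage inverts back).
    """
    if not isinstance(scene, SceneConfig):
        raise TypeError("scene must be a SceneConfig")
    W_cm, H_cm = scene.arena.width_cm, scene.arena.height_cm
    xs = np.asarray(traj.x_cm, dtype=float)
    ys = np.asarray(traj.y_cm, dtype=float)
    if np.any((xs < 0) | (xs > W_cm) | (ys < 0) | (ys > H_cm)):
        raise ValueError("trajectory point outside arena; cannot render")

    rng = _resolve_seed(seed)
    n = len(xs)
    H, W = scene.shape_px
    occluded = rng.uniform(size=n) < scene.occlusion_prob
    px = scene.px_per_cm
    sig = scene.blob_sigma_px
    half = int(math.ceil(4.0 * sig))
    frames = np.empty((n, H, W), dtype=np.uint8)

    for idx in range(n):
        if scene.background_sd > 0:
            img = rng.normal(scene.background_mean, scene.background_sd, (H, W))
        else:
            img = np.full((H, W), float(scene.background_mean))
        if not occluded[idx]:
            # pixel-centre coordinates of the marker
            cx = xs[idx] * px - 0.5
            cy = H - ys[idx] * px - 0.5
            c0 = max(0, int(math.floor(cx)) - half)
            c1 = min(W, int(math.ceil(cx)) + half + 1)
            r0 = max(0, int(math.floor(cy)) - half)
            r1 = min(H, int(math.ceil(cy)) + half + 1)
            rr, cc = np.meshgrid(
                np.arange(r0, r1), np.arange(c0, c1), indexing="ij"
            )
            blob = scene.blob_peak * np.exp(
                -((cc - cx) ** 2 + (rr - cy) ** 2) / (2.0 * sig * sig)
            )
            img[r0:r1, c0:c1] += blob
        frames[idx] = np.clip(img, 0, 255).astype(np.uint8)

    return FrameSequence(
        frames=frames,
        time_s=np.asarray(traj.time_s, dtype=float),
        px_per_cm=px,
        arena=scene.arena,
        occluded=occluded,
    )


def rest_occupancy_params(
    rest_occupancy: float, p_rest_to_move: float = 0.2, **kwargs
) -> CRWParams:
    """CRWParams whose stationary resting occupancy equals the target.

    Keeps the rest→move rate fixed and solves the move→rest rate from the
    two-state stationary balance.
    """
    if not (0.0 <= rest_occupancy < 1.0):
        raise ValueError("rest_occupancy must lie in [0, 1)")
    p_mr = rest_occupancy * p_rest_to_move / (1.0 - rest_occupancy)
    return CRWParams(p_move_to_rest=p_mr, p_rest_to_move=p_rest_to_move, **kwargs)


def generate_density_experiment(
    scenario: Mapping[str, CRWParams], n_individuals: int, seed
) -> pd.DataFrame:
    """Simulate a labelled cohort: ``n_individuals`` walkers per treatment.

    ``scenario`` maps treatment labels to the CRWParams for that level
    (identical parameter sets across levels form a valid null scenario).
    Returns a tidy trajectory table with columns ``time_s, x_cm, y_cm,
    individual_id, treatment``.
    """
    if len(scenario) < 2:
        raise ValueError("scenario needs at least 2 treatment levels")
    if n_individuals < 3:
        raise ValueError("need at least 3 individuals per treatment")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(scenario) * n_individuals)
    rows = []
    c = 0
    for label, params in scenario.items():
        if not isinstance(params, CRWParams):
            raise TypeError(f"scenario[{label!r}] must be a CRWParams")
        for i in range(n_individuals):
            traj = generate_crw(params, np.random.default_rng(children[c]))
            c += 1
            df = traj.to_frame()
            df["individual_id"] = f"{label}_{i:03d}"
            df["treatment"] = label
            rows.append(df)
    return pd.concat(rows, ignore_index=True)
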