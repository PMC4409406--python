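"""End-to-end pipeline: trajectories (or frames) → metrics → comparisons.

The pipeline is fully declarative: a :class:`PipelineConfig` (plain-text
YAML) fixes the arena geometry, filtering rules, divider configuration and
seed, and :func:`run_pipeline` executes the stages in order, writing every
intermediate table as CSV together with a manifest recording the config
hash and seed.  Re-running with the same config and seed reproduces
byte-identical outputs.

A single config seed fans out to per-stage sub-seeds through
``numpy.random.SeedSequence`` spawning, so adding a stage never perturbs
the randomness of earlier stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .compare import build_summary_table, compare_treatments
from .fractal import DividerConfig, fractal_per_individual
from .metrics import (
    REST_THRESHOLD_CM,
    fit_step_distribution,
    resting_fraction,
    step_lengths,
    stops_per_distance,
    turning_angles,
)
from .synthetic import (
    CRWParams,
    SceneConfig,
    generate_brownian,
    generate_crw,
    generate_density_experiment,
    generate_reference_path,
    render_frames,
    rest_occupancy_params,
)
from .tracking import DetectionConfig, track_sequence
from .trajectory import ArenaConfig, build_paths, filter_min_locations, summarize_paths

log = logging.getLogger("aquatrack")

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures"]

_CONFIG_KEYS = {
    "arena",
    "detection",
    "rest_threshold_cm",
    "min_locations",
    "divider",
    "seed",
    "trajectories_csv",
    "frames_dir",
    "out_dir",
}
_ARENA_KEYS = {"width_cm", "height_cm", "margin_cm", "frame_rate_hz"}
_DIVIDER_KEYS = {"delta_min_cm", "delta_max_cm", "n_dividers"}
_DETECTION_KEYS = {"px_per_cm", "k_sigma", "min_area_px", "background_exclude_top"}


@dataclass
class PipelineConfig:
    """Validated, fully serialisable pipeline settings."""

    arena: ArenaConfig = field(default_factory=ArenaConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    rest_threshold_cm: float = REST_THRESHOLD_CM
    min_locations: int = 5
    divider: DividerConfig = field(default_factory=DividerConfig)
    seed: int = 0
    trajectories_csv: str | None = None
    frames_dir: str | None = None
    out_dir: str = "aquatrack_out"

    def __post_init__(self) -> None:
        if self.rest_threshold_cm <= 0:
            raise ValueError("rest_threshold_cm must be positive")
        if self.min_locations < 2:
            raise ValueError("min_locations must be at least 2")
        if self.trajectories_csv is None and self.frames_dir is None:
            raise ValueError(
                "config must provide trajectories_csv or frames_dir"
            )

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(data)
        for key, keys, typ in [
            ("arena", _ARENA_KEYS, ArenaConfig),
            ("divider", _DIVIDER_KEYS, DividerConfig),
            ("detection", _DETECTION_KEYS, DetectionConfig),
        ]:
            if key in kw:
                sub = kw[key] or {}
                bad = set(sub) - keys
                if bad:
                    raise ValueError(f"unknown {key} config keys: {sorted(bad)}")
                kw[key] = typ(**sub)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_mapping(data)

    def to_canonical_yaml(self) -> str:
        d = {
            "arena": asdict(self.arena),
            "detection": asdict(self.detection),
            "rest_threshold_cm": self.rest_threshold_cm,
            "min_locations": self.min_locations,
            "divider": asdict(self.divider),
            "seed": self.seed,
            "trajectories_csv": self.trajectories_csv,
            "frames_dir": self.frames_dir,
            "out_dir": self.out_dir,
        }
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_yaml().encode()).hexdigest()[:16]


def segment_metrics_rows(segments, threshold_cm: float) -> list[dict]:
    rows = []
    for seg in segments:
        steps = step_lengths(seg, threshold_cm)
        rest = resting_fraction(steps)
        reloc = steps.relocation_steps
        try:
            spd = stops_per_distance(steps)
        except ValueError:
            spd = float("nan")
        verdict = fit_step_distribution(steps, x_min_cm=threshold_cm).verdict \
            if len(reloc) else "inconclusive"
        rows.append(
            {
                "individual_id": seg.individual_id,
                "treatment": seg.treatment,
                "segment_id": seg.segment_id,
                "n_points": seg.n_points,
                "n_steps": len(steps),
                "mean_step_cm": float(reloc.mean()) if len(reloc) else float("nan"),
                "resting_fraction": rest.resting_fraction,
                "stops_per_m": spd,
                "distribution_verdict": verdict,
            }
        )
    return rows


def _per_individual_metrics(
    segments_by_individual: dict, cfg: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate each individual's segments into one metrics row and a pool
    of relocation turning angles."""
    ind_rows = []
    angle_rows = []
    for (ind, treatment), segs in segments_by_individual.items():
        all_steps = []
        all_reloc = []
        n_stops = 0
        durations = []
        for seg in segs:
            s = step_lengths(seg, cfg.rest_threshold_cm)
            all_steps.append(s.step_cm)
            all_reloc.append(s.relocation_steps)
            r = s.is_relocation
            n_stops += int(np.count_nonzero(r[:-1] & ~r[1:]))
            durations.append((seg.n_points - 1) * 1.0)
            if seg.n_points >= 3:
                for th in turning_angles(seg, cfg.rest_threshold_cm).theta_deg:
                    angle_rows.append(
                        {"treatment": treatment, "individual_id": ind,
                         "angle_deg": float(th)}
                    )
        steps = np.concatenate(all_steps) if all_steps else np.array([])
        reloc = np.concatenate(all_reloc) if all_reloc else np.array([])
        dist_cm = float(reloc.sum())
        try:
            D = fractal_per_individual(
                segs, cfg.divider, min_locations=cfg.min_locations
            )
        except ValueError:
            D = float("nan")
        ind_rows.append(
            {
                "individual_id": ind,
                "treatment": treatment,
                "n_segments": len(segs),
                "resting_fraction": (
                    float(np.count_nonzero(steps < cfg.rest_threshold_cm) / len(steps))
                    if len(steps)
                    else float("nan")
                ),
                "mean_step_cm": float(reloc.mean()) if len(reloc) else float("nan"),
                "stops_per_m": (n_stops / (dist_cm / 100.0)) if dist_cm > 0 else float("nan"),
                "fractal_D": D,
                "duration_mean_s": float(np.mean(durations)) if durations else float("nan"),
            }
        )
    return pd.DataFrame(ind_rows), pd.DataFrame(
        angle_rows, columns=["treatment", "individual_id", "angle_deg"]
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write outputs under ``config.out_dir``.

    Returns the run report (also written as ``manifest.json``): the config
    hash, seed, per-stage row counts and the list of output files.
    """
    if not isinstance(config, PipelineConfig):
        raise TypeError("config must be a PipelineConfig")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    counts: dict[str, int] = {}

    # --- stage: input ---------------------------------------------------
    if config.frames_dir is not None:
        frames = aio.read_frames(config.frames_dir)
        detections = track_sequence(frames, config.detection)
        counts["frames_read"] = len(frames)
        counts["detections_present"] = sum(d.present for d in detections)
        det_path = out / "detections.csv"
        aio.write_detections(detections, det_path)
        outputs.append(det_path.name)
        traj = pd.DataFrame(
            {
                "time_s": [d.time_s for d in detections],
                "x_cm": [d.x_cm for d in detections],
                "y_cm": [d.y_cm for d in detections],
                "present": [d.present for d in detections],
            }
        )
        traj["individual_id"] = "ind0"
        traj["treatment"] = "none"
    else:
        traj = aio.read_trajectories(config.trajectories_csv)
        traj["present"] = True
    counts["trajectory_points"] = len(traj)
    log.info("input: %d trajectory points", len(traj))

    # --- stage: paths ----------------------------------------------------
    segments_by_individual: dict = {}
    all_segments = []
    kept = dropped = 0
    for (ind, treatment), grp in traj.groupby(
        ["individual_id", "treatment"], sort=False
    ):
        segs = build_paths(
            grp.sort_values("time_s"),
            config.arena,
            individual_id=str(ind),
            treatment=str(treatment),
        )
        segs = filter_min_locations(segs, config.min_locations)
        kept += sum(s.n_points for s in segs)
        dropped += len(grp) - sum(s.n_points for s in segs)
        if segs:
            segments_by_individual[(str(ind), str(treatment))] = segs
            all_segments.extend(segs)
    counts["segments"] = len(all_segments)
    counts["points_kept"] = kept
    log.info("paths: %d segments, %d points kept", len(all_segments), kept)
    seg_path = out / "segments.csv"
    aio.write_segments(all_segments, seg_path)
    outputs.append(seg_path.name)

    # per-treatment bookkeeping
    book_rows = []
    for treatment, grp in traj.groupby("treatment", sort=False):
        segs = [s for s in all_segments if s.treatment == str(treatment)]
        summ = summarize_paths(segs, len(grp))
        book_rows.append(
            {
                "treatment": str(treatment),
                "available_points_pct": summ.available_points_pct,
                "n_paths": summ.n_paths,
                "mean_duration_s": summ.mean_duration_s,
                "sd_duration_s": summ.sd_duration_s,
            }
        )
    bookkeeping = pd.DataFrame(book_rows)
    book_path = out / "path_summary.csv"
    bookkeeping.to_csv(book_path, index=False)
    outputs.append(book_path.name)

    # --- stage: metrics --------------------------------------------------
    seg_metrics = pd.DataFrame(
        segment_metrics_rows(all_segments, config.rest_threshold_cm)
    )
    segm_path = out / "segment_metrics.csv"
    seg_metrics.to_csv(segm_path, index=False)
    outputs.append(segm_path.name)

    per_ind, angles = _per_individual_metrics(segments_by_individual, config)
    ind_path = out / "individual_metrics.csv"
    per_ind.to_csv(ind_path, index=False)
    outputs.append(ind_path.name)
    ang_path = out / "turning_angles.csv"
    angles.to_csv(ang_path, index=False)
    outputs.append(ang_path.name)
    counts["individuals"] = len(per_ind)
    counts["turning_angles"] = len(angles)

    # --- stage: summary + comparisons ------------------------------------
    summary = build_summary_table(per_ind, angles, bookkeeping)
    summ_path = out / "summary_table.csv"
    summary.to_csv(summ_path)
    outputs.append(summ_path.name)

    treatments = sorted(per_ind["treatment"].unique()) if len(per_ind) else []
    if len(treatments) >= 2:
        comp_rows = []
        for metric, tbl in [
            ("resting_time", per_ind),
            ("step_length", per_ind),
            ("fractal_dimension", per_ind.dropna(subset=["fractal_D"])),
            ("turning_angle", angles),
        ]:
            try:
                comp_rows.append(compare_treatments(tbl, metric).to_dict())
            except ValueError as exc:
                log.warning("comparison %s skipped: %s", metric, exc)
        comp = pd.DataFrame(comp_rows)
        comp_path = out / "comparisons.csv"
        comp.to_csv(comp_path, index=False)
        outputs.append(comp_path.name)

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": counts,
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def make_fixtures(seed: int, out_dir) -> dict:
    """Write the packaged synthetic dataset used by tests and examples.

    Produces the analytic reference paths (straight, Koch level 5, dense
    Brownian), a two-treatment cohort differing in resting occupancy, and
    a small rendered frame sequence; returns (and writes) a manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_brownian, s_cohort, s_frames, s_crw = ss.spawn(4)
    artifacts = {}

    straight = generate_reference_path("straight", 100.0, n_points=101)
    koch = generate_reference_path("koch", 100.0, level=5)
    brown = generate_brownian(20_000, 0.1, np.random.default_rng(s_brownian))
    for name, traj in [("straight", straight), ("koch_level5", koch),
                       ("brownian", brown)]:
        path = out / f"reference_{name}.csv"
        df = traj.to_frame()
        df["individual_id"] = name
        df["treatment"] = "reference"
        aio.write_trajectories(df, path)
        artifacts[f"reference_{name}"] = path.name

    scenario = {
        "low_density": rest_occupancy_params(0.3, n_steps=900),
        "high_density": rest_occupancy_params(0.6, n_steps=900),
    }
    cohort = generate_density_experiment(
        scenario, n_individuals=5, seed=s_cohort
    )
    cohort_path = out / "cohort.csv"
    aio.write_trajectories(cohort, cohort_path)
    artifacts["cohort"] = cohort_path.name

    arena = ArenaConfig(width_cm=40.0, height_cm=40.0, margin_cm=4.0)
    scene = SceneConfig(arena=arena, px_per_cm=5.0, occlusion_prob=0.1)
    walk = generate_crw(
        CRWParams(n_steps=59, start_xy_cm=(20.0, 20.0), arena=arena),
        np.random.default_rng(s_crw),
    )
    frames = render_frames(walk, scene, np.random.default_rng(s_frames))
    frames_dir = out / "frames"
    aio.write_frames(frames, frames_dir)
    truth_path = out / "frames_truth.csv"
    df = walk.to_frame()
    df["individual_id"] = "rendered"
    df["treatment"] = "fixture"
    aio.write_trajectories(df, truth_path)
    artifacts["frames"] = frames_dir.name
    artifacts["frames_truth"] = truth_path.name

    manifest = {"seed": seed, "artifacts": artifacts}
    (out / "fixtures_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
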