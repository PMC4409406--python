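"""CSV and frame-directory I/O.

All tabular interchange uses plain UTF-8 CSV with a header row and point
decimals.  Frame sequences are directories of 8-bit grayscale PNGs with a
plain-text sidecar (``scene.txt``) carrying the pixel scale and arena
size, which the tracking stage requires.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synthetic import FrameSequence, Trajectory
from .tracking import Detection
from .trajectory import ArenaConfig, PathSegment

TRAJECTORY_COLUMNS = ["time_s", "x_cm", "y_cm", "individual_id", "treatment"]
DETECTION_COLUMNS = ["time_s", "x_cm", "y_cm", "present", "blob_area_px"]
SEGMENT_COLUMNS = TRAJECTORY_COLUMNS + ["segment_id"]


def write_trajectories(df: pd.DataFrame, path) -> None:
    df[TRAJECTORY_COLUMNS].to_csv(path, index=False)


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    return df


def write_detections(detections: list[Detection], path) -> None:
    pd.DataFrame(
        [
            {
                "time_s": d.time_s,
                "x_cm": d.x_cm,
                "y_cm": d.y_cm,
                "present": d.present,
                "blob_area_px": d.blob_area_px,
            }
            for d in detections
        ],
        columns=DETECTION_COLUMNS,
    ).to_csv(path, index=False)


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detection CSV missing columns: {sorted(missing)}")
    df["present"] = df["present"].astype(bool)
    return df


def write_segments(segments: list[PathSegment], path) -> None:
    frames = []
    for seg in segments:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": seg.time_s,
                    "x_cm": seg.x_cm,
                    "y_cm": seg.y_cm,
                    "individual_id": seg.individual_id,
                    "treatment": seg.treatment,
                    "segment_id": seg.segment_id,
                }
            )
        )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=SEGMENT_COLUMNS)
    )
    out[SEGMENT_COLUMNS].to_csv(path, index=False)


def read_segments(path) -> list[PathSegment]:
    df = pd.read_csv(path)
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"segment CSV missing columns: {sorted(missing)}")
    segments = []
    for (ind, seg_id), grp in df.groupby(["individual_id", "segment_id"], sort=False):
        grp = grp.sort_values("time_s")
        segments.append(
            PathSegment(
                grp["time_s"].to_numpy(float),
                grp["x_cm"].to_numpy(float),
                grp["y_cm"].to_numpy(float),
                individual_id=str(ind),
                treatment=str(grp["treatment"].iloc[0]),
                segment_id=int(seg_id),
            )
        )
    return segments


def write_frames(frames: FrameSequence, outdir) -> None:
    """One PNG per frame plus a plain-text sidecar with the scale metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i in range(len(frames)):
        iio.imwrite(outdir / f"frame_{i:06d}.png", frames.frames[i])
    sidecar = outdir / "scene.txt"
    sidecar.write_text(
        "px_per_cm = {:g}\n"
        "width_cm = {:g}\n"
        "height_cm = {:g}\n"
        "frame_rate_hz = {:g}\n".format(
            frames.px_per_cm,
            frames.arena.width_cm,
            frames.arena.height_cm,
            frames.arena.frame_rate_hz,
        )
    )


def read_frames(indir) -> FrameSequence:
    indir = Path(indir)
    sidecar = indir / "scene.txt"
    if not sidecar.exists():
        raise ValueError(f"missing scale sidecar {sidecar}")
    meta = {}
    for line in sidecar.read_text().splitlines():
        if "=" in line:
            key, val = line.split("=", 1)
            meta[key.strip()] = float(val.strip())
    arena = ArenaConfig(
        width_cm=meta.get("width_cm", 100.0),
        height_cm=meta.get("height_cm", 100.0),
        frame_rate_hz=meta.get("frame_rate_hz", 1.0),
    )
    paths = sorted(indir.glob("frame_*.png"))
    if not paths:
        raise ValueError(f"no frame_*.png files in {indir}")
    imgs = np.stack([iio.imread(p) for p in paths])
    return FrameSequence(
        frames=imgs,
        time_s=np.arange(len(paths), dtype=float) / arena.frame_rate_hz,
        px_per_cm=meta["px_per_cm"],
        arena=arena,
        occluded=np.zeros(len(paths), dtype=bool),
    )


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    return traj.to_frame()
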