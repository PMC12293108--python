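"""Reading and writing the package's on-disk formats.

Movies are multi-page TIFF (tifffile); trajectories and survival tables
are CSV (pandas); masks are 8-bit TIFF/PNG; configuration is YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import MovieStack, Track, TrajectorySet

__all__ = [
    "read_movie",
    "write_movie",
    "read_tracks_csv",
    "write_tracks_csv",
    "read_mask",
    "load_config",
    "save_config",
]


def read_movie(path, pixel_size: float, frame_interval: float) -> MovieStack:
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        frames = frames[None]
    return MovieStack(frames.astype(float), pixel_size, frame_interval)


def write_movie(path, movie: MovieStack) -> None:
    tifffile.imwrite(str(path), movie.frames.astype(np.float32),
                     photometric="minisblack")


def write_tracks_csv(path, ts: TrajectorySet,
                     states: dict[int, np.ndarray] | None = None) -> None:
    """Columns: track_id, frame, x_um, y_um, intensity[, state]."""
    rows = []
    for t in ts.tracks:
        inten = t.intensity if t.intensity is not None else np.full(len(t), np.nan)
        for i in range(len(t)):
            row = {"track_id": t.track_id, "frame": int(t.frames[i]),
                   "x_um": t.xy[i, 0], "y_um": t.xy[i, 1],
                   "intensity": inten[i]}
            if states is not None and t.track_id in states:
                row["state"] = int(states[t.track_id][i])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks_csv(path, frame_interval: float, pixel_size: float,
                    regime: str = "fast") -> TrajectorySet:
    df = pd.read_csv(path)
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        inten = grp["intensity"].to_numpy() if "intensity" in grp else None
        tracks.append(Track(int(tid), grp["frame"].to_numpy(),
                            grp[["x_um", "y_um"]].to_numpy(), inten))
    ts = TrajectorySet(tracks, frame_interval, pixel_size, regime)
    ts.log(f"read_tracks_csv: {len(tracks)} tracks from {path}")
    return ts


def read_mask(path) -> np.ndarray:
    from imageio.v3 import imread
    arr = imread(str(path)) if str(path).endswith(".png") else tifffile.imread(str(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
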