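"""Core in-memory containers shared across the package.

Conventions
-----------
* Physical coordinates are in micrometres, with the origin at the image
  corner; the centre of pixel ``(row i, col j)`` sits at
  ``((j + 0.5) * pixel_size, (i + 0.5) * pixel_size)``.
* Frame indices are 0-based and strictly increasing within a track.
* A track present for ``k`` frames at frame interval ``dt`` has duration
  ``k * dt`` (a molecule seen in k frames was present at least that long).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "MovieStack",
    "Localization",
    "Track",
    "TrajectorySet",
    "px_to_um",
    "um_to_px",
]


def px_to_um(px: np.ndarray | float, pixel_size: float):
    """Pixel index -> physical coordinate of the pixel centre (um)."""
    return (np.asarray(px, dtype=float) + 0.5) * pixel_size


def um_to_px(um: np.ndarray | float, pixel_size: float):
    """Physical coordinate (um) -> fractional pixel index."""
    return np.asarray(um, dtype=float) / pixel_size - 0.5


@dataclass
class MovieStack:
    """A time-lapse image stack with its spatial/temporal calibration.

    frames : (t, y, x) float array of intensities
    pixel_size : um per pixel
    frame_interval : s per frame
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (t, y, x) array")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def fov(self) -> tuple[float, float]:
        """Field of view (x_um, y_um)."""
        return (self.frames.shape[2] * self.pixel_size,
                self.frames.shape[1] * self.pixel_size)


class Localization(NamedTuple):
    """A single subpixel detection: frame index, position (um), intensity."""

    frame: int
    x: float
    y: float
    intensity: float


@dataclass
class Track:
    """One molecule's time-ordered subpixel positions.

    frames : (n,) int array, strictly increasing
    xy : (n, 2) float array of positions in um
    intensity : optional (n,) array
    """

    track_id: int
    frames: np.ndarray
    xy: np.ndarray
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be (n, 2)")
        if len(self.frames) != len(self.xy):
            raise ValueError("frames and xy must have equal length")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def length(self) -> int:
        """Number of frames the molecule was observed in."""
        return len(self.frames)

    def duration(self, frame_interval: float) -> float:
        """Observed lifetime in seconds (length * frame interval)."""
        return self.length * frame_interval

    def max_span_from_origin(self) -> float:
        """Maximum displacement (um) from the first localization."""
        d = self.xy - self.xy[0]
        return float(np.sqrt((d ** 2).sum(axis=1)).max())


@dataclass
class TrajectorySet:
    """A collection of tracks plus acquisition metadata and a provenance log."""

    tracks: list[Track]
    frame_interval: float
    pixel_size: float
    regime: str = "fast"  # "fast" | "slow"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.track_id for t in self.tracks]
        if len(ids) != len(set(ids)):
            raise ValueError("track_ids must be unique")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def durations(self) -> np.ndarray:
        """Observed track durations in seconds."""
        return np.array([t.duration(self.frame_interval) for t in self.tracks])

    def with_tracks(self, tracks: list[Track], note: str | None = None) -> "TrajectorySet":
        out = TrajectorySet(tracks, self.frame_interval, self.pixel_size,
                            self.regime, list(self.provenance))
        if note:
            out.log(note)
        return out
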