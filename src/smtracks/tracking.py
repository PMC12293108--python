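"""Particle detection, trajectory linking and trajectory filtering.

Detection: band-pass (difference of Gaussians) + local-maximum search in
a detection box, followed by subpixel refinement with a least-squares 2D
Gaussian fit whose position is constrained to within 1.5 px of the
initial maximum.

Linking: greedy nearest-neighbour assignment per frame pair with a hard
distance gate and optional gap closing.  At the sparse emitter densities
required for single-molecule tracking this coincides with full
multiple-target tracing; track durations and displacements — the
quantities analysed downstream — do not depend on crowded-scene
disambiguation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares
from skimage.feature import peak_local_max

from .core import Localization, MovieStack, Track, TrajectorySet
from .mobility import compute_msd, estimate_track_diffusion

__all__ = [
    "DetectionParams",
    "FilterConfig",
    "detect_particles",
    "detect_stack",
    "link_trajectories",
    "filter_fast_tracks",
    "filter_slow_tracks",
    "split_by_mask",
]


@dataclass(frozen=True)
class DetectionParams:
    """box_size: local-maximum search box (px); threshold: absolute
    band-pass threshold, or None for a robust automatic one;
    max_refinement_px: Gaussian-fit position constraint (px)."""

    box_size: int = 7
    sigma_small: float = 1.0
    sigma_large: float = 3.0
    threshold: float | None = None
    auto_k: float = 5.0
    max_refinement_px: float = 1.5
    psf_sigma_px: float = 1.3


@dataclass(frozen=True)
class FilterConfig:
    """Trajectory filters: track length window [min_length, max_length]
    frames, maximum travel from the track origin (um), and — for the slow
    regime — the maximum expected diffusion coefficient (um^2/s)."""

    min_length: int = 8
    max_length: int = 1000
    max_travel: float = 5.0
    d_max_slow: float = 0.1
    drop_short_slow: bool = True  # tracks too short for a D estimate

    def __post_init__(self) -> None:
        if self.min_length < 2:
            raise ValueError("min_length must be >= 2")
        if self.max_travel <= 0:
            raise ValueError("max_travel must be > 0")


def _auto_threshold(bp: np.ndarray, k: float) -> float:
    med = np.median(bp)
    mad = np.median(np.abs(bp - med))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:  # noise-free image: scale to the brightest feature
        peak = bp.max()
        return med + 0.1 * (peak - med) if peak > med else np.inf
    return med + k * robust_sd


def _fit_gaussian_2d(patch: np.ndarray, x0_px: float, y0_px: float,
                     max_shift: float, sigma0: float):
    """Least-squares 2D Gaussian on a patch; returns (x, y, amplitude) in
    patch pixel coordinates or None when the fit fails."""
    ny, nx = patch.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    off0 = float(patch.min())
    amp0 = float(patch.max() - off0)
    if amp0 <= 0:
        return None

    def resid(p):
        a, x, y, s, o = p
        model = a * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * s ** 2)) + o
        return (model - patch).ravel()

    lo = [0.0, x0_px - max_shift, y0_px - max_shift, 0.3, -np.inf]
    hi = [np.inf, x0_px + max_shift, y0_px + max_shift, max(nx, ny), np.inf]
    try:
        sol = least_squares(resid, [amp0, x0_px, y0_px, sigma0, off0],
                            bounds=(lo, hi))
    except Exception:
        return None
    if not sol.success:
        return None
    a, x, y, s, o = sol.x
    return x, y, a * 2 * np.pi * s ** 2


def detect_particles(frame: np.ndarray, pixel_size: float,
                     params: DetectionParams = DetectionParams(),
                     frame_index: int = 0) -> list[Localization]:
    """Detect diffraction-limited emitters in one frame.

    Returns subpixel localizations in micrometres (pixel centres at
    ``(i + 0.5) * pixel_size``).  A flat frame yields an empty list.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    if np.ptp(frame) == 0:
        return []
    bp = gaussian_filter(frame, params.sigma_small) - gaussian_filter(
        frame, params.sigma_large)
    thr = params.threshold if params.threshold is not None else _auto_threshold(
        bp, params.auto_k)
    if not np.isfinite(thr):
        return []
    peaks = peak_local_max(bp, min_distance=params.box_size // 2,
                           threshold_abs=thr, exclude_border=1)
    half = params.box_size // 2
    out: list[Localization] = []
    for iy, ix in peaks:
        y0, y1 = max(0, iy - half), min(frame.shape[0], iy + half + 1)
        x0, x1 = max(0, ix - half), min(frame.shape[1], ix + half + 1)
        patch = frame[y0:y1, x0:x1]
        fit = _fit_gaussian_2d(patch, ix - x0, iy - y0,
                               params.max_refinement_px, params.psf_sigma_px)
        if fit is None:
            continue
        fx, fy, photons = fit
        out.append(Localization(frame_index,
                                (x0 + fx + 0.5) * pixel_size,
                                (y0 + fy + 0.5) * pixel_size,
                                float(photons)))
    return out


def detect_stack(movie: MovieStack,
                 params: DetectionParams = DetectionParams()) -> dict[int, list[Localization]]:
    """Run detection over every frame of a stack."""
    return {f: detect_particles(movie.frames[f], movie.pixel_size, params, f)
            for f in range(movie.n_frames)}


def link_trajectories(locs_by_frame: dict[int, list[Localization]],
                      max_disp: float, max_gap: int = 0,
                      frame_interval: float = 0.02, pixel_size: float = 0.1,
                      regime: str = "fast") -> TrajectorySet:
    """Greedy nearest-neighbour linking with a hard distance gate.

    Candidate (track, localization) pairs within ``max_disp`` um are
    linked shortest-distance-first; each localization joins at most one
    track; a track ends after ``max_gap`` consecutive missed frames.
    """
    if max_disp < 0 or max_gap < 0:
        raise ValueError("gates must be non-negative")
    active: list[dict] = []
    done: list[dict] = []
    next_id = 0
    for f in sorted(locs_by_frame):
        locs = locs_by_frame[f]
        # retire tracks that can no longer link
        still = []
        for tr in active:
            if f - tr["frames"][-1] > max_gap + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        pairs = []
        for ti, tr in enumerate(active):
            lx, ly = tr["xy"][-1]
            for li, loc in enumerate(locs):
                d = np.hypot(loc.x - lx, loc.y - ly)
                if d <= max_disp:
                    pairs.append((d, ti, li))
        pairs.sort()
        used_t: set[int] = set()
        used_l: set[int] = set()
        for d, ti, li in pairs:
            if ti in used_t or li in used_l:
                continue
            used_t.add(ti)
            used_l.add(li)
            tr = active[ti]
            loc = locs[li]
            tr["frames"].append(f)
            tr["xy"].append((loc.x, loc.y))
            tr["intensity"].append(loc.intensity)
        for li, loc in enumerate(locs):
            if li not in used_l:
                active.append({"id": next_id, "frames": [f],
                               "xy": [(loc.x, loc.y)],
                               "intensity": [loc.intensity]})
                next_id += 1
    done.extend(active)
    tracks = [Track(tr["id"], np.array(tr["frames"]), np.array(tr["xy"]),
                    np.array(tr["intensity"])) for tr in done]
    tracks.sort(key=lambda t: t.track_id)
    ts = TrajectorySet(tracks, frame_interval, pixel_size, regime)
    ts.log(f"link_trajectories: {len(tracks)} tracks "
           f"(max_disp={max_disp}, max_gap={max_gap})")
    return ts


def filter_fast_tracks(ts: TrajectorySet,
                       cfg: FilterConfig = FilterConfig()) -> TrajectorySet:
    """Length-window and travel-distance filters for the fast regime."""
    kept = [t for t in ts.tracks
            if cfg.min_length <= t.length <= cfg.max_length
            and t.max_span_from_origin() <= cfg.max_travel]
    return ts.with_tracks(
        kept, f"filter_fast_tracks: {len(ts.tracks)} -> {len(kept)} "
              f"(length in [{cfg.min_length}, {cfg.max_length}], "
              f"travel <= {cfg.max_travel} um)")


def filter_slow_tracks(ts: TrajectorySet,
                       cfg: FilterConfig = FilterConfig(),
                       n_fit_points: int = 4) -> TrajectorySet:
    """Keep tracks whose estimated D stays below the slow-regime bound.

    Tracks too short for a D estimate (< 3 frames) are dropped by default
    (``cfg.drop_short_slow``) and counted in provenance.
    """
    kept = []
    n_short = 0
    for t in ts.tracks:
        if len(t) < 3:
            n_short += 1
            if not cfg.drop_short_slow:
                kept.append(t)
            continue
        d = estimate_track_diffusion(compute_msd(t, n_fit_points),
                                     n_fit_points, ts.frame_interval)
        if d <= cfg.d_max_slow:
            kept.append(t)
    return ts.with_tracks(
        kept, f"filter_slow_tracks: {len(ts.tracks)} -> {len(kept)} "
              f"(D <= {cfg.d_max_slow} um^2/s; {n_short} too short, "
              f"{'dropped' if cfg.drop_short_slow else 'kept'})")


def split_by_mask(ts: TrajectorySet, mask: np.ndarray,
                  min_inside_fraction: float = 0.5):
    """Split tracks by a binary region mask on the movie pixel grid.

    A track is "inside" when at least ``min_inside_fraction`` of its
    localizations fall on mask-true pixels.  Returns
    (inside TrajectorySet, outside TrajectorySet).
    """
    mask = np.asarray(mask).astype(bool)
    inside_tracks, outside_tracks = [], []
    for t in ts.tracks:
        jj = np.clip((t.xy[:, 0] / ts.pixel_size).astype(int), 0, mask.shape[1] - 1)
        ii = np.clip((t.xy[:, 1] / ts.pixel_size).astype(int), 0, mask.shape[0] - 1)
        frac = mask[ii, jj].mean() if len(t) else 0.0
        (inside_tracks if frac >= min_inside_fraction else outside_tracks).append(t)
    inside = ts.with_tracks(inside_tracks,
                            f"split_by_mask: {len(inside_tracks)} inside")
    outside = ts.with_tracks(outside_tracks,
                             f"split_by_mask: {len(outside_tracks)} outside")
    return inside, outside
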