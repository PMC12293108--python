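"""Fast-regime mobility analysis: MSD, diffusion coefficients, histograms.

Per-track mean squared displacement (time-averaged over all overlapping
position pairs), a per-track diffusion coefficient from a linear fit of
the first few MSD points (the intercept absorbs static localization
error), the per-cell log10-D mobility histogram, mobile/immobile
classification at a fixed log10 threshold, and the ensemble MSD with its
area under the curve (AUC), a scalar mobility summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Track, TrajectorySet

__all__ = [
    "MSDCurve",
    "MobilityConfig",
    "MobilitySummary",
    "compute_msd",
    "estimate_track_diffusion",
    "mobility_distribution",
    "classify_mobile_immobile",
    "ensemble_msd_and_auc",
    "summarize_mobility",
]


@dataclass
class MSDCurve:
    """MSD(lag) with the pair count behind each lag."""

    lags: np.ndarray  # s, strictly increasing, excludes lag 0
    msd: np.ndarray  # um^2
    n_pairs: np.ndarray

    def __len__(self) -> int:
        return len(self.lags)


@dataclass(frozen=True)
class MobilityConfig:
    """Defaults follow standard fast-SMT practice at 20 ms exposure:
    10 MSD points, log10 D in [-5, 1] with 0.1 bins, mobile/immobile
    threshold at log10 D = -1.45 (~0.035 um^2/s), D fitted from the
    first 4 MSD points."""

    n_msd_points: int = 10
    msd_time_interval: float = 0.02
    log10_d_min: float = -5.0
    log10_d_max: float = 1.0
    bin_width: float = 0.1
    mobile_threshold_log10: float = -1.45
    n_fit_points: int = 4

    def __post_init__(self) -> None:
        if not (self.log10_d_min < self.mobile_threshold_log10 < self.log10_d_max):
            raise ValueError("need log10_d_min < threshold < log10_d_max")


@dataclass
class MobilitySummary:
    """Per-cell mobility metrics."""

    d_values: np.ndarray
    hist_edges: np.ndarray
    hist_freq: np.ndarray  # normalized to sum to 1
    mobile_fraction: float
    mobile_immobile_ratio: float
    ensemble_msd: MSDCurve
    auc: float
    n_tracks: int
    n_excluded: int
    notes: list[str] = field(default_factory=list)


def compute_msd(track: Track, max_lag_points: int | None = None) -> MSDCurve:
    """Time-averaged MSD over all overlapping pairs at each lag.

    ``MSD(k) = mean_i |r(i+k) - r(i)|^2`` in squared micrometres; the lag
    axis is returned in *frames* here and scaled to seconds by callers
    that know the frame interval.
    """
    n = len(track)
    if n < 2:
        raise ValueError("track must have >= 2 points")
    max_k = n - 1
    if max_lag_points is not None:
        if max_lag_points >= n:
            warnings.warn(f"max_lag_points={max_lag_points} >= track length {n}; "
                          "truncating", stacklevel=2)
        max_k = min(max_k, max_lag_points)
    xy = track.xy
    lags = np.arange(1, max_k + 1)
    msd = np.empty(max_k)
    npairs = np.empty(max_k, dtype=int)
    for k in lags:
        d = xy[k:] - xy[:-k]
        msd[k - 1] = np.mean((d ** 2).sum(axis=1))
        npairs[k - 1] = n - k
    return MSDCurve(lags.astype(float), msd, npairs)


def estimate_track_diffusion(msd: MSDCurve, n_fit_points: int = 4,
                             frame_interval: float = 1.0) -> float:
    """D from an unweighted linear fit MSD(tau) = 4 D tau + b.

    Uses the first ``n_fit_points`` lags (fewer if the curve is shorter,
    minimum 2).  The fitted D may be <= 0 for noise-dominated tracks;
    downstream histogramming excludes those.
    """
    m = min(n_fit_points, len(msd))
    if m < 2:
        raise ValueError("need at least 2 MSD points to fit D")
    tau = msd.lags[:m] * frame_interval
    y = msd.msd[:m]
    slope, _ = np.polyfit(tau, y, 1)
    return float(slope / 4.0)


def _track_ds(ts: TrajectorySet, cfg: MobilityConfig) -> np.ndarray:
    ds = []
    for tr in ts.tracks:
        if len(tr) < 3:
            continue
        msd = compute_msd(tr, min(cfg.n_fit_points, len(tr) - 1))
        ds.append(estimate_track_diffusion(msd, cfg.n_fit_points,
                                           ts.frame_interval))
    return np.asarray(ds)


def _range_filter(ds: np.ndarray, cfg: MobilityConfig):
    ds = np.asarray(ds, dtype=float)
    positive = ds > 0
    logd = np.full_like(ds, -np.inf)
    logd[positive] = np.log10(ds[positive])
    keep = positive & (logd >= cfg.log10_d_min) & (logd <= cfg.log10_d_max)
    return ds[keep], logd[keep], int((~keep).sum())


def mobility_distribution(ds, cfg: MobilityConfig = MobilityConfig()):
    """Normalized log10-D histogram.

    Non-positive D and values outside [log10_d_min, log10_d_max] are
    excluded (their count is returned); frequencies sum to 1.
    Returns (edges, frequencies, n_used, n_excluded).
    """
    _, logd, n_excl = _range_filter(ds, cfg)
    if logd.size == 0:
        raise ValueError("no tracks inside the log10 D range")
    n_bins = int(round((cfg.log10_d_max - cfg.log10_d_min) / cfg.bin_width))
    edges = cfg.log10_d_min + cfg.bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(logd, bins=edges)
    return edges, counts / counts.sum(), int(logd.size), n_excl


def classify_mobile_immobile(ds, threshold_log10: float = -1.45,
                             cfg: MobilityConfig = MobilityConfig()):
    """Mobile fraction and mobile:immobile ratio at a log10 D threshold.

    Mobile means log10 D > threshold (default -1.45, i.e. ~0.035 um^2/s).
    With zero immobile tracks the ratio is reported as ``inf``; the
    fraction is always valid.
    """
    _, logd, _ = _range_filter(ds, cfg)
    if logd.size == 0:
        raise ValueError("no tracks inside the log10 D range")
    mobile = int((logd > threshold_log10).sum())
    immobile = int(logd.size - mobile)
    frac = mobile / logd.size
    ratio = np.inf if immobile == 0 else mobile / immobile
    return float(frac), float(ratio)


def ensemble_msd_and_auc(ts: TrajectorySet,
                         cfg: MobilityConfig = MobilityConfig()):
    """Per-cell mean MSD over the first ``n_msd_points`` lags, plus AUC.

    Tracks shorter than the requested number of lags contribute the lags
    they have (per-lag track counts are returned in the curve).  AUC is
    the trapezoidal integral of the mean MSD over the lag axis (um^2 s).
    """
    n_lag = cfg.n_msd_points
    acc = np.zeros(n_lag)
    cnt = np.zeros(n_lag, dtype=int)
    for tr in ts.tracks:
        if len(tr) < 2:
            continue
        msd = compute_msd(tr, min(n_lag, len(tr) - 1))
        k = len(msd)
        acc[:k] += msd.msd
        cnt[:k] += 1
    have = cnt > 0
    if not have.any():
        raise ValueError("no tracks long enough for an ensemble MSD")
    lags_s = cfg.msd_time_interval * np.arange(1, n_lag + 1)[have]
    mean_msd = acc[have] / cnt[have]
    curve = MSDCurve(lags_s, mean_msd, cnt[have])
    auc = float(np.trapezoid(mean_msd, lags_s))
    return curve, auc


def summarize_mobility(ts: TrajectorySet,
                       cfg: MobilityConfig = MobilityConfig()) -> MobilitySummary:
    """Full per-cell mobility summary from a filtered fast-regime set."""
    ds = _track_ds(ts, cfg)
    edges, freq, n_used, n_excl = mobility_distribution(ds, cfg)
    frac, ratio = classify_mobile_immobile(ds, cfg.mobile_threshold_log10, cfg)
    curve, auc = ensemble_msd_and_auc(ts, cfg)
    return MobilitySummary(ds, edges, freq, frac, ratio, curve, auc,
                           n_tracks=len(ts.tracks), n_excluded=n_excl,
                           notes=[f"{n_used} tracks in histogram"])
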