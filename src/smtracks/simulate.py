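"""Synthetic single-molecule data with known ground truth.

Generates the inputs every downstream stage consumes: two-state
(free/bound) Brownian trajectories with photobleaching, dwell-duration
samples from exponential / exponential-mixture / bounded power-law
families, rendered single-molecule movies, and raster-scanned confocal
time series of diffusing emitters.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
configs and seeds give bit-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .core import MovieStack, Track, TrajectorySet

__all__ = [
    "DwellSpec",
    "TwoStateSimConfig",
    "GroundTruth",
    "RasterScanConfig",
    "simulate_two_state_tracks",
    "simulate_dwell_durations",
    "render_movie",
    "simulate_raster_scan",
]

FREE, BOUND = 0, 1


@dataclass(frozen=True)
class DwellSpec:
    """Generative family for bound-state dwell durations.

    family : "single_exp" | "exp_mixture" | "power_law"
    For exponentials, ``taus`` are time constants (s) and ``fractions``
    their weights (sum to 1).  For the power law, durations follow a
    bounded Pareto with survival exponent ``alpha`` on
    ``[t_min, t_max]`` (density exponent 1 + alpha).
    """

    family: str
    taus: tuple[float, ...] = ()
    fractions: tuple[float, ...] = ()
    alpha: float = 0.0
    t_min: float = 0.0
    t_max: float = 0.0

    def __post_init__(self) -> None:
        if self.family == "single_exp":
            if len(self.taus) != 1 or self.taus[0] <= 0:
                raise ValueError("single_exp needs one positive tau")
        elif self.family == "exp_mixture":
            if len(self.taus) < 2 or len(self.taus) != len(self.fractions):
                raise ValueError("exp_mixture needs matching taus/fractions")
            if any(t <= 0 for t in self.taus):
                raise ValueError("taus must be > 0")
            if any(f <= 0 for f in self.fractions) or abs(sum(self.fractions) - 1) > 1e-9:
                raise ValueError("fractions must be positive and sum to 1")
        elif self.family == "power_law":
            if self.alpha <= 0:
                raise ValueError("alpha must be > 0")
            if not (0 < self.t_min < self.t_max):
                raise ValueError("need 0 < t_min < t_max")
        else:
            raise ValueError(f"unknown family {self.family!r}")

    @classmethod
    def single_exp(cls, tau: float) -> "DwellSpec":
        return cls("single_exp", taus=(float(tau),), fractions=(1.0,))

    @classmethod
    def exp_mixture(cls, fractions, taus) -> "DwellSpec":
        return cls("exp_mixture", taus=tuple(map(float, taus)),
                   fractions=tuple(map(float, fractions)))

    @classmethod
    def power_law(cls, alpha: float, t_min: float, t_max: float) -> "DwellSpec":
        return cls("power_law", alpha=float(alpha), t_min=float(t_min),
                   t_max=float(t_max))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n dwell durations (s)."""
        if self.family == "single_exp":
            return rng.exponential(self.taus[0], size=n)
        if self.family == "exp_mixture":
            comp = rng.choice(len(self.taus), size=n, p=self.fractions)
            return rng.exponential(np.asarray(self.taus)[comp])
        # bounded Pareto via inverse CDF: S(t) = (t^-a - tmax^-a)/(tmin^-a - tmax^-a)
        u = rng.uniform(size=n)
        a, lo, hi = self.alpha, self.t_min ** -self.alpha, self.t_max ** -self.alpha
        return (lo - u * (lo - hi)) ** (-1.0 / a)


@dataclass(frozen=True)
class TwoStateSimConfig:
    """Two-state (free <-> bound) Brownian motion under photobleaching.

    d_free, d_bound : diffusion coefficients, um^2/s
    k_bind, k_unbind : switching rates, 1/s (k_unbind ignored when
        ``bound_dwell`` overrides the exponential unbinding clock)
    frame_interval : s; n_frames, n_molecules : counts
    fov : (x_um, y_um) field of view; pixel_size : um
    bleach_rate : 1/s (0 disables bleaching)
    p_free0 : initial probability of the free state; defaults to the
        stationary distribution of the two-state chain.
    """

    d_free: float = 3.5
    d_bound: float = 0.003
    k_bind: float = 2.0
    k_unbind: float = 2.0
    bound_dwell: DwellSpec | None = None
    frame_interval: float = 0.02
    n_frames: int = 6000
    n_molecules: int = 100
    fov: tuple[float, float] = (20.0, 20.0)
    pixel_size: float = 0.1
    bleach_rate: float = 0.0
    p_free0: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("d_free", "d_bound", "k_bind", "k_unbind", "bleach_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be > 0")
        if self.fov[0] <= 0 or self.fov[1] <= 0:
            raise ValueError("fov must be positive")
        if self.p_free0 is not None and not (0 <= self.p_free0 <= 1):
            raise ValueError("p_free0 must be in [0, 1]")


@dataclass
class GroundTruth:
    """Per-molecule truth for a two-state simulation.

    states : list of (n_i,) int arrays (0 free / 1 bound) at frame starts
    bound_durations : list of arrays of continuous bound run lengths (s),
        truncated at the end of observation (bleach or movie end)
    bound_censored : parallel bool arrays; True where the run was cut by
        the end of observation rather than by unbinding
    bleach_times : (n_molecules,) array (inf if never bleached)
    positions : list of (n_i, 2) arrays, um
    """

    states: list[np.ndarray] = field(default_factory=list)
    bound_durations: list[np.ndarray] = field(default_factory=list)
    bound_censored: list[np.ndarray] = field(default_factory=list)
    bleach_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    positions: list[np.ndarray] = field(default_factory=list)

    def all_bound_durations(self, complete_only: bool = False) -> np.ndarray:
        durs, cens = self.bound_durations, self.bound_censored
        if not durs:
            return np.empty(0)
        if complete_only:
            return np.concatenate(
                [d[~c] for d, c in zip(durs, cens)] or [np.empty(0)])
        return np.concatenate(list(durs) or [np.empty(0)])


def _stationary_p_free(cfg: TwoStateSimConfig) -> float:
    if cfg.k_bind == 0 and cfg.k_unbind == 0:
        return 1.0
    return cfg.k_unbind / (cfg.k_bind + cfg.k_unbind)


def _state_intervals(cfg: TwoStateSimConfig, t_end: float, start_free: bool,
                     rng: np.random.Generator):
    """Alternating (state, duration, censored) intervals on [0, t_end]."""
    t = 0.0
    state = FREE if start_free else BOUND
    out = []
    while t < t_end:
        if state == FREE:
            dur = rng.exponential(1 / cfg.k_bind) if cfg.k_bind > 0 else np.inf
        elif cfg.bound_dwell is not None:
            dur = float(cfg.bound_dwell.sample(1, rng)[0])
        else:
            dur = rng.exponential(1 / cfg.k_unbind) if cfg.k_unbind > 0 else np.inf
        censored = dur > t_end - t
        out.append((state, min(dur, t_end - t), censored))
        t += dur
        state = BOUND if state == FREE else FREE
    return out


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (handles multiple bounces)."""
    width = hi - lo
    y = np.mod(x - lo, 2 * width)
    y = np.where(y > width, 2 * width - y, y)
    return y + lo


def simulate_two_state_tracks(cfg: TwoStateSimConfig):
    """Simulate molecules switching between free and bound diffusion.

    Positions take per-frame Gaussian steps with per-axis variance
    ``2 * D_state * dt`` (state evaluated at the frame start); tracks end
    at the bleach time (exponential) or the last frame, whichever comes
    first; boundaries are reflecting.

    Returns (TrajectorySet, GroundTruth).
    """
    rng = np.random.default_rng(cfg.seed)
    p_free = _stationary_p_free(cfg) if cfg.p_free0 is None else cfg.p_free0
    dt = cfg.frame_interval
    t_total = cfg.n_frames * dt

    tracks: list[Track] = []
    truth = GroundTruth(bleach_times=np.full(cfg.n_molecules, np.inf))

    for m in range(cfg.n_molecules):
        start_free = rng.uniform() < p_free
        if cfg.bleach_rate > 0:
            t_bleach = rng.exponential(1 / cfg.bleach_rate)
        else:
            t_bleach = np.inf
        truth.bleach_times[m] = t_bleach
        # number of observed frames: frame i is seen if its start i*dt < t_bleach
        n_obs = cfg.n_frames if not np.isfinite(t_bleach) else int(
            min(cfg.n_frames, np.ceil(t_bleach / dt)))
        n_obs = max(n_obs, 1) if t_bleach > 0 else 0
        t_trunc = min(t_total, t_bleach)
        intervals = _state_intervals(cfg, t_trunc, start_free, rng)
        truth.bound_durations.append(
            np.array([d for s, d, _ in intervals if s == BOUND]))
        truth.bound_censored.append(
            np.array([c for s, _, c in intervals if s == BOUND], dtype=bool))

        if n_obs == 0:
            truth.states.append(np.empty(0, dtype=int))
            truth.positions.append(np.empty((0, 2)))
            continue

        # state at each frame start
        edges = np.cumsum([d for _, d, _ in intervals])
        frame_t = np.arange(n_obs) * dt
        idx = np.searchsorted(edges, frame_t, side="right")
        idx = np.minimum(idx, len(intervals) - 1)
        states = np.array([intervals[i][0] for i in idx], dtype=int)

        d_per_frame = np.where(states == FREE, cfg.d_free, cfg.d_bound)
        sigma = np.sqrt(2.0 * d_per_frame[:-1] * dt) if n_obs > 1 else np.empty(0)
        steps = rng.standard_normal((max(n_obs - 1, 0), 2)) * sigma[:, None] if n_obs > 1 \
            else np.empty((0, 2))
        xy = np.empty((n_obs, 2))
        xy[0] = [rng.uniform(0, cfg.fov[0]), rng.uniform(0, cfg.fov[1])]
        if n_obs > 1:
            xy[1:] = xy[0] + np.cumsum(steps, axis=0)
            xy[:, 0] = _reflect(xy[:, 0], 0.0, cfg.fov[0])
            xy[:, 1] = _reflect(xy[:, 1], 0.0, cfg.fov[1])

        truth.states.append(states)
        truth.positions.append(xy)
        tracks.append(Track(m, np.arange(n_obs), xy))

    ts = TrajectorySet(tracks, dt, cfg.pixel_size,
                       regime="fast" if dt < 0.1 else "slow")
    ts.log(f"simulate_two_state_tracks: {len(tracks)} tracks, seed={cfg.seed}")
    return ts, truth


def simulate_dwell_durations(spec: DwellSpec, bleach_rate: float,
                             frame_interval: float, n: int, seed: int = 0,
                             rng: np.random.Generator | None = None):
    """Observed dwell durations under competing photobleaching.

    Each true dwell competes with an exponential bleach clock; the
    observed duration is the minimum, recorded as ``ceil(t/dt) * dt``
    frames of presence.

    Returns ``(durations, bleached)`` where ``bleached[i]`` is True when
    the bleach clock, not unbinding, ended observation i.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    if bleach_rate < 0:
        raise ValueError("bleach_rate must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    true_dwell = spec.sample(n, rng)
    if bleach_rate > 0:
        t_bleach = rng.exponential(1 / bleach_rate, size=n)
    else:
        t_bleach = np.full(n, np.inf)
    observed = np.minimum(true_dwell, t_bleach)
    bleached = t_bleach < true_dwell
    durations = np.ceil(observed / frame_interval) * frame_interval
    durations = np.maximum(durations, frame_interval)  # zero-length guard
    return durations, bleached


def _gaussian_pixel_integral(x0, y0, sigma, photons, shape, pixel_size, radius=5.0):
    """Photon counts of a 2D Gaussian integrated over pixels (erf quadrature)."""
    ny, nx = shape
    img = np.zeros(shape)
    s = sigma * np.sqrt(2.0)
    jx0, iy0 = x0 / pixel_size, y0 / pixel_size
    r = int(np.ceil(radius * sigma / pixel_size)) + 1
    j_lo, j_hi = max(0, int(jx0) - r), min(nx, int(jx0) + r + 1)
    i_lo, i_hi = max(0, int(iy0) - r), min(ny, int(iy0) + r + 1)
    if j_lo >= j_hi or i_lo >= i_hi:
        return img
    xe = np.arange(j_lo, j_hi + 1) * pixel_size
    ye = np.arange(i_lo, i_hi + 1) * pixel_size
    fx = 0.5 * (erf((xe[1:] - x0) / s) - erf((xe[:-1] - x0) / s))
    fy = 0.5 * (erf((ye[1:] - y0) / s) - erf((ye[:-1] - y0) / s))
    img[i_lo:i_hi, j_lo:j_hi] = photons * np.outer(fy, fx)
    return img


def render_movie(ts: TrajectorySet, psf_sigma: float, photons_per_frame: float,
                 background_mean: float = 0.0, noise_model: str = "poisson",
                 seed: int = 0, fov: tuple[float, float] | None = None) -> MovieStack:
    """Render a trajectory set into a camera movie.

    Each localization becomes a 2D Gaussian PSF of width ``psf_sigma`` (um)
    integrated over the pixel grid with total ``photons_per_frame`` photons;
    a constant ``background_mean`` is added and, with
    ``noise_model="poisson"``, every pixel is Poisson-sampled.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    if noise_model not in ("poisson", "none"):
        raise ValueError("noise_model must be 'poisson' or 'none'")
    rng = np.random.default_rng(seed)
    ps = ts.pixel_size
    if fov is None:
        hi = max((t.xy.max() for t in ts.tracks if len(t)), default=1.0)
        fov = (hi + 1.0, hi + 1.0)
    nx, ny = int(np.ceil(fov[0] / ps)), int(np.ceil(fov[1] / ps))
    n_frames = 1 + max((int(t.frames[-1]) for t in ts.tracks if len(t)), default=0)
    frames = np.full((n_frames, ny, nx), float(background_mean))
    for tr in ts.tracks:
        for f, (x, y) in zip(tr.frames, tr.xy):
            frames[f] += _gaussian_pixel_integral(x, y, psf_sigma,
                                                  photons_per_frame, (ny, nx), ps)
    if noise_model == "poisson":
        frames = rng.poisson(frames).astype(float)
    return MovieStack(frames, ps, ts.frame_interval)


@dataclass(frozen=True)
class RasterScanConfig:
    """Raster-scanned confocal acquisition of freely diffusing particles.

    d : um^2/s; particle_density : 1/um^2; pixel_dwell / line_time : s;
    pixel_size : um; w0/wz : lateral/axial beam waists, um;
    frame_size : pixels per side; brightness : mean photons per particle
    per pixel dwell at beam centre.
    """

    d: float = 1.0
    particle_density: float = 0.5
    pixel_dwell: float = 12.5e-6
    line_time: float = 4.313e-3
    pixel_size: float = 0.041
    w0: float = 0.25
    wz: float = 1.5
    frame_size: int = 128
    n_frames: int = 100
    brightness: float = 5.0
    background: float = 0.0
    seed: int = 0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.d < 0 or self.particle_density < 0 or self.brightness < 0:
            raise ValueError("d, particle_density, brightness must be >= 0")
        if self.line_time < self.frame_size * self.pixel_dwell:
            raise ValueError("line_time must cover frame_size * pixel_dwell")
        if not (0 < self.w0 < self.wz):
            raise ValueError("need 0 < w0 < wz")


def simulate_raster_scan(cfg: RasterScanConfig) -> MovieStack:
    """Raster-scan a field of diffusing point emitters.

    Particles perform 2D Brownian motion in a periodic box the size of the
    scan field; each line samples the instantaneous Gaussian-illumination
    intensity ``B * exp(-2 r^2 / w0^2)`` at that line's acquisition time
    (particle motion within one line, ~tens of us of pixel dwells, is
    negligible at these scan timings and is not resolved).  Shot noise is
    Poisson.
    """
    rng = np.random.default_rng(cfg.seed)
    npx = cfg.frame_size
    size = npx * cfg.pixel_size  # um, square field
    n_part = rng.poisson(cfg.particle_density * size * size)
    frames = np.zeros((cfg.n_frames, npx, npx))
    xpix = (np.arange(npx) + 0.5) * cfg.pixel_size

    pos = rng.uniform(0, size, size=(n_part, 2))
    sigma_line = np.sqrt(2.0 * cfg.d * cfg.line_time)
    cut = 3.5 * cfg.w0
    for f in range(cfg.n_frames):
        for row in range(npx):
            if f or row:  # first line defines t=0
                pos = np.mod(pos + rng.standard_normal((n_part, 2)) * sigma_line, size)
            if n_part:
                y_row = (row + 0.5) * cfg.pixel_size
                dy = pos[:, 1] - y_row
                dy -= size * np.round(dy / size)  # minimum-image wrap
                near = np.abs(dy) < cut
                if near.any():
                    dx = pos[near, 0][:, None] - xpix[None, :]
                    dx -= size * np.round(dx / size)
                    g = np.exp(-2.0 * (dx ** 2 + dy[near, None] ** 2) / cfg.w0 ** 2)
                    frames[f, row] += cfg.brightness * g.sum(axis=0)
    frames += cfg.background
    if cfg.shot_noise:
        frames = rng.poisson(frames).astype(float)
    return MovieStack(frames, cfg.pixel_size, npx * cfg.line_time)
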