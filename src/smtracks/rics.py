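"""Raster image correlation spectroscopy (RICS).

Extracts an ensemble diffusion coefficient from the spatial
autocorrelation of raster-scanned confocal time series.  Because the
scanner visits pixels sequentially (pixel dwell tau_p along a line, line
time tau_l between lines), spatial lags carry a hidden time lag
``tau(xi, psi) = tau_p |xi| + tau_l |psi|``, and the decay of the
correlation surface along the two axes encodes diffusion on the
microsecond (fast axis) and millisecond (line axis) timescales.

The one-component free-diffusion model fitted here is

    G(xi, psi) = (gamma / N) * (1 + 4 D tau / w0^2)^-1
                 * (1 + 4 D tau / wz^2)^-1/2
                 * exp(-dr^2 (xi^2 + psi^2) / (w0^2 (1 + 4 D tau / w0^2)))
                 + offset

with gamma the focal-volume shape factor (0.3536 for a 3D Gaussian), N
the mean number of particles in the focal volume, w0/wz the lateral and
axial beam waists and dr the pixel size.  Passing ``wz=inf`` drops the
axial factor (appropriate for planar/2D samples and simulations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import MovieStack

__all__ = [
    "ACFSurface",
    "RICSFit",
    "moving_average_subtract",
    "compute_acf",
    "fit_one_component",
    "rics_model",
]

GAMMA_3D_GAUSSIAN = 0.3536


def moving_average_subtract(stack: MovieStack, window: int = 10) -> MovieStack:
    """Remove slow intensity trends with a centred moving-average subtraction.

    From each frame the per-pixel moving average over ``window`` frames
    (truncated at the ends of the series) is subtracted and the global
    mean added back, preserving the mean intensity the ACF normalization
    relies on.  Immobile structure and bleaching ramps are removed;
    fluctuations faster than the window survive.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    n = stack.n_frames
    if n < window:
        raise ValueError(f"need >= {window} frames, got {n}")
    csum = np.cumsum(stack.frames, axis=0)
    zero = np.zeros_like(csum[:1])
    csum = np.concatenate([zero, csum], axis=0)
    half_lo = (window - 1) // 2
    half_hi = window // 2
    lo = np.maximum(np.arange(n) - half_lo, 0)
    hi = np.minimum(np.arange(n) + half_hi + 1, n)
    local_mean = (csum[hi] - csum[lo]) / (hi - lo)[:, None, None]
    out = stack.frames - local_mean + stack.frames.mean()
    return MovieStack(out, stack.pixel_size, stack.frame_interval)


@dataclass
class ACFSurface:
    """Frame-averaged 2D fluctuation autocorrelation of a raster series.

    g : correlation values, fftshifted so g[n//2, n//2] is zero lag
    xi, psi : pixel-lag axes (fast/scan axis and line axis)
    pixel_dwell, line_time, pixel_size : scan metadata used by the fit
    """

    g: np.ndarray
    xi: np.ndarray
    psi: np.ndarray
    pixel_dwell: float
    line_time: float
    pixel_size: float
    n_frames: int = 0

    def zero_lag_index(self) -> tuple[int, int]:
        return len(self.psi) // 2, len(self.xi) // 2


def compute_acf(stack: MovieStack, pixel_dwell: float,
                line_time: float) -> ACFSurface:
    """Normalized spatial autocorrelation, averaged over frames.

    Per frame: ``G(xi, psi) = <dI(x, y) dI(x+xi, y+psi)> / <I>^2`` with
    ``dI = I - <I>``, computed via FFT (circular boundary).  Frames are
    averaged; the zero-lag value contains the shot-noise spike and is
    excluded from fitting downstream.
    """
    frames = stack.frames
    n_f, ny, nx = frames.shape
    acc = np.zeros((ny, nx))
    for f in range(n_f):
        img = frames[f]
        mean = img.mean()
        if mean == 0:
            raise ValueError(f"frame {f} has zero mean; cannot normalize")
        d = img - mean
        F = np.fft.fft2(d)
        corr = np.fft.ifft2(F * np.conj(F)).real / (img.size * mean ** 2)
        acc += corr
    g = np.fft.fftshift(acc / n_f)
    xi = np.arange(nx) - nx // 2
    psi = np.arange(ny) - ny // 2
    return ACFSurface(g, xi, psi, pixel_dwell, line_time, stack.pixel_size,
                      n_frames=n_f)


def rics_model(xi, psi, d, n_particles, offset, *, w0, wz, pixel_dwell,
               line_time, pixel_size, gamma=GAMMA_3D_GAUSSIAN):
    """Evaluate the one-component diffusion model at pixel lags (xi, psi)."""
    tau = pixel_dwell * np.abs(xi) + line_time * np.abs(psi)
    k = 1.0 + 4.0 * d * tau / w0 ** 2
    axial = np.ones_like(k) if not np.isfinite(wz) else \
        (1.0 + 4.0 * d * tau / wz ** 2) ** -0.5
    spatial = np.exp(-pixel_size ** 2 * (xi ** 2 + psi ** 2) / (w0 ** 2 * k))
    return (gamma / n_particles) / k * axial * spatial + offset


@dataclass
class RICSFit:
    """One-component RICS fit result."""

    d: float  # um^2/s
    n_particles: float
    offset: float
    w0: float
    wz: float
    gamma: float
    sse: float
    converged: bool
    residuals: np.ndarray | None = None


def fit_one_component(acf: ACFSurface, w0: float = 0.25, wz: float = 1.5,
                      fit_radius: tuple[int, int] = (32, 8),
                      gamma: float = GAMMA_3D_GAUSSIAN) -> RICSFit:
    """Least-squares fit of the one-component diffusion model.

    Fits D, N and a constant offset over lags ``|xi| <= fit_radius[0]``,
    ``|psi| <= fit_radius[1]``, excluding zero lag (shot noise).  The beam
    waists are calibration inputs, not fitted.
    """
    rx, ry = fit_radius
    sel_x = np.abs(acf.xi) <= rx
    sel_y = np.abs(acf.psi) <= ry
    XI, PSI = np.meshgrid(acf.xi[sel_x], acf.psi[sel_y])
    G = acf.g[np.ix_(sel_y, sel_x)]
    mask = ~((XI == 0) & (PSI == 0))
    xi, psi, g = XI[mask].astype(float), PSI[mask].astype(float), G[mask]

    g_peak = max(float(np.max(g)), 1e-12)
    kwargs = dict(w0=w0, wz=wz, pixel_dwell=acf.pixel_dwell,
                  line_time=acf.line_time, pixel_size=acf.pixel_size,
                  gamma=gamma)

    def resid(p):
        log_d, log_n, off = p
        return rics_model(xi, psi, np.exp(log_d), np.exp(log_n), off,
                          **kwargs) - g

    best, best_cost = None, np.inf
    for d0 in (0.1, 1.0, 10.0):
        p0 = [np.log(d0), np.log(gamma / g_peak), 0.0]
        try:
            sol = least_squares(resid, p0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
    if best is None:
        return RICSFit(np.nan, np.nan, np.nan, w0, wz, gamma, np.inf,
                       converged=False)
    d = float(np.exp(best.x[0]))
    n = float(np.exp(best.x[1]))
    return RICSFit(d, n, float(best.x[2]), w0, wz, gamma,
                   float(np.sum(best.fun ** 2)), converged=bool(best.success),
                   residuals=best.fun)
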