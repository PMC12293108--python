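"""Publication-style diagnostic plots (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_mobility_histogram", "plot_survival", "plot_acf_fit"]


def plot_mobility_histogram(edges, freq, threshold=-1.45, ax=None, **kw):
    """Log10-D relative-frequency histogram with the mobile/immobile cut."""
    if ax is None:
        _, ax = plt.subplots()
    centers = 0.5 * (edges[:-1] + edges[1:])
    ax.bar(centers, freq, width=edges[1] - edges[0], **kw)
    ax.axvline(threshold, ls="--", color="k", lw=1)
    ax.set_xlabel(r"log$_{10}$ D ($\mu$m$^2$/s)")
    ax.set_ylabel("relative frequency")
    return ax


def plot_survival(surv, fits=(), ci_band=None, ax=None, labels=None):
    """Log-log survival curve with model fits and an optional CI band."""
    if ax is None:
        _, ax = plt.subplots()
    ax.loglog(surv.times, surv.survival, ".", ms=4, label="data")
    for i, fit in enumerate(fits):
        lab = labels[i] if labels else fit.family
        ax.loglog(surv.times, fit.predict(surv.times), "-", label=lab)
    if ci_band is not None:
        lo, hi = ci_band
        ax.fill_between(surv.times, lo, hi, alpha=0.2, label="99% CI")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("1 - CDF")
    ax.legend(frameon=False)
    return ax


def plot_acf_fit(acf, fit, axline=0):
    """Central fast-axis ACF slice, the model, and residuals above."""
    from .rics import rics_model
    fig, (ax_res, ax) = plt.subplots(
        2, 1, sharex=True, height_ratios=[1, 3], figsize=(5, 4))
    iy, _ = acf.zero_lag_index()
    row = acf.g[iy + axline]
    model = rics_model(acf.xi.astype(float), float(axline), fit.d,
                       fit.n_particles, fit.offset, w0=fit.w0, wz=fit.wz,
                       pixel_dwell=acf.pixel_dwell, line_time=acf.line_time,
                       pixel_size=acf.pixel_size, gamma=fit.gamma)
    ax.plot(acf.xi, row, ".", ms=3, label="ACF")
    ax.plot(acf.xi, model, "-", label=f"fit D={fit.d:.2f}")
    ax_res.plot(acf.xi, row - model, ".", ms=2)
    ax_res.axhline(0, color="k", lw=0.5)
    ax.set_xlabel(r"$\xi$ (pixels)")
    ax.set_ylabel(r"G($\xi$, 0)")
    ax_res.set_ylabel("resid.")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig
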