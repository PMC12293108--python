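"""Residence-time (dwell-time) survival analysis for slow-regime tracking.

The slow acquisition regime (long exposures) blurs out diffusing
molecules, so surviving tracks report how long individual molecules stay
bound to chromatin.  This module turns track durations into an empirical
survival distribution ``S(t) = P(duration >= t)``, truncates its noisy
tail, removes the apparent shortening caused by fluorophore
photobleaching (calibrated from a stably bound control such as histone
H2B), fits competing dwell-time models — exponential mixtures and a power
law — and selects among them with the Bayesian information criterion.

Model conventions
-----------------
* Exponential mixture: ``S(t) = sum_i f_i exp(-t / tau_i)`` with
  ``sum f_i = 1``; a k-component fit has ``2k - 1`` free parameters.
* Power law: ``S(t) = A (t / t_ref)^(-alpha)`` with ``alpha`` the
  negative log-log slope of the *survival* function (smaller alpha =
  longer-lived binding); the dwell-time density exponent is ``1 + alpha``.
* BIC is computed from the (weighted) Gaussian-residual SSE on the
  log-survival curve: ``BIC = m ln(SSE / m) + p ln m`` over the m fitted
  points.  All models compared by :func:`select_model` must be fitted on
  the identical truncated survival so their SSEs are commensurable.
* Track durations are frame counts times the frame interval, so the
  empirical survival at ``k * dt`` equals the continuous-time survival at
  ``(k - 1) * dt``.  With ``frame_discretized=True`` the fits evaluate
  their model at ``t - dt`` (dropping the first, identically-1 point),
  which makes parameter estimates consistent with the generative clock.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "SurvivalDistribution",
    "ExpMixtureFit",
    "PowerLawFit",
    "BleachCalibration",
    "build_survival",
    "truncate_low_counts",
    "bleach_correct",
    "fit_exp_mixture",
    "fit_power_law",
    "fit_exp_mixture_mle",
    "fit_power_law_mle",
    "calibrate_bleach",
    "select_model",
    "summarize_dwell",
    "bootstrap_ci",
]


@dataclass
class SurvivalDistribution:
    """Empirical complement-CDF of track durations on the frame grid.

    times : k * dt for k = 1..K (s)
    survival : P(duration >= t), non-increasing, survival[0] == 1 before
        any truncation/correction
    events_remaining : cumulative event counts #{durations >= t}
    n_total : number of durations compiled
    dt : frame interval (s)
    """

    times: np.ndarray
    survival: np.ndarray
    events_remaining: np.ndarray
    n_total: int
    dt: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.events_remaining = np.asarray(self.events_remaining)

    def __len__(self) -> int:
        return len(self.times)


def build_survival(durations, dt: float) -> SurvivalDistribution:
    """Compile durations (multiples of dt) into a survival distribution.

    ``survival(k dt) = #{durations >= k dt} / n`` evaluated at every
    multiple of dt up to the longest duration.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size == 0:
        raise ValueError("no durations supplied")
    if np.any(durations < dt - 1e-9):
        raise ValueError("all durations must be >= dt")
    k = np.maximum(np.round(durations / dt).astype(int), 1)
    K = int(k.max())
    hist = np.bincount(k, minlength=K + 1)
    counts = hist[::-1].cumsum()[::-1][1:]  # counts[j-1] = #{k >= j}
    times = dt * np.arange(1, K + 1)
    return SurvivalDistribution(times, counts / durations.size, counts,
                                int(durations.size), dt)


def truncate_low_counts(surv: SurvivalDistribution,
                        min_events: int = 30) -> SurvivalDistribution:
    """Drop time points with fewer than ``min_events`` cumulative events.

    ``min_events=0`` is the identity (the all-points mode used for paired
    condensate / non-punctate comparisons on small track sets).
    """
    keep = surv.events_remaining >= min_events
    if not keep.any():
        raise ValueError(
            f"all {len(surv)} time points fall below {min_events} events")
    return SurvivalDistribution(surv.times[keep], surv.survival[keep],
                                surv.events_remaining[keep], surv.n_total,
                                surv.dt)


def bleach_correct(surv: SurvivalDistribution,
                   k_bleach: float) -> SurvivalDistribution:
    """Undo exponential photobleaching: ``S_corr = S_obs * exp(k_b (t - t1))``.

    The corrected curve is renormalized so the first point is 1.  An
    increasing corrected survival (over-correction beyond counting noise,
    i.e. a rise exceeding 3 sigma of the local binomial error) is flagged
    with a warning, never silently clipped.
    """
    if k_bleach < 0:
        raise ValueError("k_bleach must be >= 0")
    t1 = surv.times[0]
    corr = surv.survival * np.exp(k_bleach * (surv.times - t1))
    if corr[0] <= 0:
        raise ValueError("survival at the first time point is not positive")
    corr = corr / corr[0]
    noise = corr / np.sqrt(np.maximum(surv.events_remaining, 1))
    rises = np.diff(corr) > 3.0 * noise[1:]
    if rises.any():
        warnings.warn(
            f"bleach correction (k={k_bleach:.4g}/s) produced a rising "
            f"survival at {int(rises.sum())} of {len(corr) - 1} steps "
            "(beyond counting noise); the bleach rate may exceed the true one",
            stacklevel=2)
    return SurvivalDistribution(surv.times, corr, surv.events_remaining,
                                surv.n_total, surv.dt)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class ExpMixtureFit:
    """A fitted k-component exponential-mixture survival model."""

    n_components: int
    fractions: np.ndarray  # sorted to match taus (descending tau)
    taus: np.ndarray
    sse: float
    bic: float
    n_points: int
    converged: bool
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    family: str = "exp_mixture"
    bic_mode: str = "curve"  # "curve" (log-survival SSE) or "mle"

    @property
    def n_params(self) -> int:
        return 2 * self.n_components - 1

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.sum(self.fractions[:, None]
                      * np.exp(-t[None, :] / self.taus[:, None]), axis=0)


@dataclass
class PowerLawFit:
    """A fitted power-law survival model ``A (t / t_ref)^(-alpha)``."""

    alpha: float
    amplitude: float
    t_ref: float
    t_start: float
    t_end: float
    sse: float
    bic: float
    n_points: int
    converged: bool = True
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    family: str = "power_law"
    bic_mode: str = "curve"

    @property
    def n_params(self) -> int:
        return 2

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude * (np.asarray(t, dtype=float) / self.t_ref) ** (-self.alpha)


def _bic(sse: float, m: int, p: int) -> float:
    return m * np.log(max(sse, 1e-300) / m) + p * np.log(m)


def _fit_points(surv: SurvivalDistribution, frame_discretized: bool,
                weight_by_counts: bool):
    """(t_model, log S, weights, m) used by every fitter.

    With ``frame_discretized`` the model abscissa is ``t - dt`` and the
    first grid point (identically 1) is dropped; weights are
    sqrt(cumulative events) since var(log S) ~ 1/counts.
    """
    t = surv.times
    s = surv.survival
    c = surv.events_remaining.astype(float)
    keep = s > 0
    if frame_discretized:
        keep &= t > surv.dt + 1e-12
    t, s, c = t[keep], s[keep], c[keep]
    if t.size == 0:
        raise ValueError("no usable survival points")
    t_model = t - surv.dt if frame_discretized else t
    w = np.sqrt(c) if weight_by_counts else np.ones_like(c)
    w = w / w.max()
    return t_model, np.log(s), w, t.size


def _default_tau_grid(surv: SurvivalDistribution, n: int = 5) -> np.ndarray:
    return np.geomspace(max(surv.dt, surv.times[0]), surv.times[-1], n)


def _stick_break(u: np.ndarray) -> np.ndarray:
    """Map k-1 unit-interval variables to a k-simplex of fractions."""
    f, rest = [], 1.0
    for ui in u:
        f.append(rest * ui)
        rest *= (1.0 - ui)
    f.append(rest)
    return np.asarray(f)


def fit_exp_mixture(surv: SurvivalDistribution, n_components: int = 2,
                    frame_discretized: bool = False,
                    weight_by_counts: bool = True,
                    tau_grid: np.ndarray | None = None) -> ExpMixtureFit:
    """Fit ``S(t) = sum f_i exp(-t/tau_i)`` by bounded nonlinear least squares.

    Residuals are taken on the log-survival curve; time constants are
    optimized in log space and fractions through a stick-breaking map so
    the simplex constraint holds exactly.  Multi-start over a log-spaced
    tau grid guards against local minima; the lowest-SSE start wins.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    t, y, w, m = _fit_points(surv, frame_discretized, weight_by_counts)
    if m < 2 * n_components + 1:
        raise ValueError(
            f"need >= {2 * n_components + 1} points for {n_components} components")
    k = n_components

    def resid(theta):
        taus = np.exp(theta[:k])
        fracs = _stick_break(1 / (1 + np.exp(-theta[k:]))) if k > 1 else np.array([1.0])
        model = fracs[:, None] * np.exp(-t[None, :] / taus[:, None])
        return w * (np.log(np.maximum(model.sum(axis=0), 1e-300)) - y)

    if tau_grid is None:
        tau_grid = _default_tau_grid(surv)
    lo = np.concatenate([np.full(k, np.log(surv.dt / 10.0)), np.full(k - 1, -8.0)])
    hi = np.concatenate([np.full(k, np.log(surv.times[-1] * 100.0)), np.full(k - 1, 8.0)])

    best, best_cost = None, np.inf
    starts = itertools.combinations(tau_grid, k) if k > 1 else [(g,) for g in tau_grid]
    for taus0 in starts:
        theta0 = np.concatenate([np.log(np.asarray(taus0)), np.zeros(k - 1)])
        try:
            sol = least_squares(resid, theta0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
    if best is None:
        return ExpMixtureFit(k, np.full(k, np.nan), np.full(k, np.nan),
                             np.inf, np.inf, m, converged=False)

    taus = np.exp(best.x[:k])
    fracs = _stick_break(1 / (1 + np.exp(-best.x[k:]))) if k > 1 else np.array([1.0])
    order = np.argsort(taus)[::-1]
    taus, fracs = taus[order], fracs[order]
    sse = float(np.sum(best.fun ** 2))
    return ExpMixtureFit(k, fracs, taus, sse, _bic(sse, m, 2 * k - 1), m,
                         converged=bool(best.success))


def fit_power_law(surv: SurvivalDistribution,
                  frame_discretized: bool = False,
                  weight_by_counts: bool = True,
                  points_per_decade: int | None = None) -> PowerLawFit:
    """Fit ``S(t) = A (t/t_ref)^(-alpha)`` by least squares of log S on log t.

    ``points_per_decade`` optionally decimates the linear-in-t grid to
    approximately uniform log-time spacing before fitting (a log-log plot
    equal-weights decades; the raw grid concentrates on the tail).
    Non-positive survival values are excluded.
    """
    t, y, w, _ = _fit_points(surv, frame_discretized, weight_by_counts)
    if t.size < 4 or t[-1] / t[0] < 10.0:
        warnings.warn("power-law fit on < 4 points or < 1 decade of time",
                      stacklevel=2)
    x = np.log(t)
    if points_per_decade is not None:
        targets = np.arange(x[0], x[-1] + 1e-9, np.log(10.0) / points_per_decade)
        idx = np.unique(np.searchsorted(x, targets))
        idx = idx[idx < len(x)]
        x, y, w = x[idx], y[idx], w[idx]
    t_ref = float(np.exp(x[0]))
    m = len(x)
    A = np.vstack([x - x[0], np.ones(m)]).T
    sol, *_ = np.linalg.lstsq(A * w[:, None], y * w, rcond=None)
    slope, intercept = sol
    res = (A @ sol - y) * w
    sse = float(np.sum(res ** 2))
    return PowerLawFit(alpha=float(-slope), amplitude=float(np.exp(intercept)),
                       t_ref=t_ref, t_start=float(np.exp(x[0])),
                       t_end=float(np.exp(x[-1])), sse=sse,
                       bic=_bic(sse, m, 2), n_points=m)


# -- duration-level maximum-likelihood fits -------------------------------
#
# Survival points are cumulative counts and therefore strongly correlated:
# Gaussian-SSE BIC on the curve treats every point as independent
# information and systematically over-rewards flexible models.  The fits
# below maximize the exact multinomial likelihood of the frame-discretized
# durations (iid observations), for which BIC = -2 lnL + p ln n is
# consistent; they are the recommended basis for family selection.


def _duration_counts(durations, dt: float):
    k = np.maximum(np.round(np.asarray(durations, float) / dt).astype(int), 1)
    counts = np.bincount(k)
    ks = np.nonzero(counts)[0]
    return ks, counts[ks], int(k.sum() * 0 + k.size)


def fit_exp_mixture_mle(durations, dt: float, n_components: int = 2,
                        bleach_rate: float = 0.0) -> ExpMixtureFit:
    """ML fit of an exponential mixture to frame-discretized durations.

    The observed survival is ``S_obs(t) = sum_i f_i e^{-t/tau_i} *
    e^{-kb t}`` (an independent exponential bleach clock, rate ``kb``,
    competes with unbinding), so a k-frame duration has probability
    ``P(k) = S_obs((k-1) dt) - S_obs(k dt)``.  The reported taus are the
    intrinsic (bleach-free) time constants.
    """
    from scipy.optimize import minimize

    ks, nk, n = _duration_counts(durations, dt)
    kk = n_components

    def nll(theta):
        rates = 1.0 / np.exp(theta[:kk]) + bleach_rate
        fracs = _stick_break(1 / (1 + np.exp(-theta[kk:]))) if kk > 1 \
            else np.array([1.0])
        lam = dt * rates
        s_lo = np.sum(fracs[:, None] * np.exp(-np.outer(lam, ks - 1)), axis=0)
        s_hi = np.sum(fracs[:, None] * np.exp(-np.outer(lam, ks)), axis=0)
        return -np.sum(nk * np.log(np.maximum(s_lo - s_hi, 1e-300)))

    t_hi = max(ks.max() * dt, 10 * dt)
    grid = np.geomspace(dt, t_hi, 5)
    starts = itertools.combinations(grid, kk) if kk > 1 else [(g,) for g in grid]
    best, best_val = None, np.inf
    for taus0 in starts:
        theta0 = np.concatenate([np.log(np.asarray(taus0)), np.zeros(kk - 1)])
        sol = minimize(nll, theta0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-9})
        if sol.fun < best_val:
            best, best_val = sol, sol.fun
    taus = np.exp(best.x[:kk])
    fracs = _stick_break(1 / (1 + np.exp(-best.x[kk:]))) if kk > 1 \
        else np.array([1.0])
    order = np.argsort(taus)[::-1]
    p = 2 * kk - 1
    return ExpMixtureFit(kk, fracs[order], taus[order], sse=np.nan,
                         bic=2 * best_val + p * np.log(n), n_points=n,
                         converged=bool(best.success), bic_mode="mle")


def fit_power_law_mle(durations, dt: float,
                      bleach_rate: float = 0.0) -> PowerLawFit:
    """ML fit of a power-law dwell model to frame-discretized durations.

    Intrinsic survival ``S(t) = (t / t0)^(-alpha)`` for ``t >= t0``
    (1 below), with ``t0 <= dt`` a fitted lower cutoff; an independent
    bleach clock multiplies it by ``e^{-kb t}``.
    """
    from scipy.optimize import minimize

    ks, nk, n = _duration_counts(durations, dt)

    def surv(t, alpha, t0):
        s = np.where(t > t0, (np.maximum(t, t0) / t0) ** -alpha, 1.0)
        return s * np.exp(-bleach_rate * t)

    def nll(theta):
        alpha = np.exp(theta[0])
        t0 = dt / (1 + np.exp(-theta[1]))  # t0 in (0, dt]
        s_lo = surv((ks - 1) * dt, alpha, t0)
        s_hi = surv(ks * dt, alpha, t0)
        return -np.sum(nk * np.log(np.maximum(s_lo - s_hi, 1e-300)))

    best, best_val = None, np.inf
    for a0 in (0.3, 0.7, 1.2):
        sol = minimize(nll, [np.log(a0), 0.0], method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-7, "fatol": 1e-9})
        if sol.fun < best_val:
            best, best_val = sol, sol.fun
    alpha = float(np.exp(best.x[0]))
    t0 = float(dt / (1 + np.exp(-best.x[1])))
    return PowerLawFit(alpha=alpha, amplitude=1.0, t_ref=t0, t_start=dt,
                       t_end=float(ks.max() * dt), sse=np.nan,
                       bic=2 * best_val + 2 * np.log(n), n_points=n,
                       converged=bool(best.success), bic_mode="mle")


@dataclass
class BleachCalibration:
    """Photobleach rate extracted from a stably bound control.

    The control survival is fitted with 2- and 3-component exponential
    mixtures; BIC selects between them and the smallest rate (longest
    time constant) of the winner is taken as the dye bleach rate — the
    control's intrinsic unbinding is assumed much slower than bleaching.
    """

    source: str
    rates: np.ndarray
    amplitudes: np.ndarray
    k_bleach: float
    bics: dict[int, float]
    n_components: int


def calibrate_bleach(control_surv: SurvivalDistribution,
                     source: str = "H2B",
                     frame_discretized: bool = False) -> BleachCalibration:
    """Estimate the bleach rate from a control (e.g. histone H2B) survival."""
    fits = {k: fit_exp_mixture(control_surv, k, frame_discretized=frame_discretized)
            for k in (2, 3)}
    bics = {k: f.bic for k, f in fits.items() if f.converged}
    if not bics:
        raise RuntimeError("bleach calibration fits did not converge")
    k_sel = min(bics, key=bics.get)
    sel = fits[k_sel]
    k_bleach = 1.0 / sel.taus[0]  # taus sorted descending -> smallest rate
    if not (k_bleach > 0):
        raise RuntimeError("selected smallest rate is not positive")
    return BleachCalibration(source, 1.0 / sel.taus, sel.fractions,
                             float(k_bleach), bics, k_sel)


def select_model(fits) -> tuple[object, pd.DataFrame]:
    """Pick the minimum-BIC model among fits on the identical survival.

    Ties break toward fewer parameters.  Returns the winning fit and a
    comparison table with delta-BIC relative to it.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits supplied")
    if len({f.n_points for f in fits}) != 1:
        raise ValueError("fits were made on different truncated survivals")
    if len({f.bic_mode for f in fits}) != 1:
        raise ValueError("cannot mix curve-SSE and MLE BIC values")
    order = sorted(fits, key=lambda f: (round(f.bic, 9), f.n_params))
    best = order[0]
    table = pd.DataFrame({
        "family": [f.family for f in fits],
        "n_params": [f.n_params for f in fits],
        "sse": [f.sse for f in fits],
        "bic": [f.bic for f in fits],
    })
    table["delta_bic"] = table["bic"] - best.bic
    return best, table


def summarize_dwell(fit: ExpMixtureFit) -> tuple[float, float, float]:
    """(tau_long, tau_short, f_long) from a two-component fit."""
    if fit.n_components != 2:
        raise ValueError("summarize_dwell needs a 2-component fit")
    taus, fracs = fit.taus, fit.fractions  # sorted descending by tau
    if taus[1] > 0 and taus[0] / taus[1] < 1.1:
        warnings.warn("time constants within 10% of each other: "
                      "the two components are degenerate", stacklevel=2)
    return float(taus[0]), float(taus[1]), float(fracs[0])


def _dwell_point_estimates(durations, dt, *, k_bleach, min_events, family,
                           n_components, frame_discretized, weight_by_counts,
                           points_per_decade) -> dict[str, float]:
    surv = truncate_low_counts(build_survival(durations, dt), min_events)
    if k_bleach > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            surv = bleach_correct(surv, k_bleach)
    if family == "power_law":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_power_law(surv, frame_discretized=frame_discretized,
                                weight_by_counts=weight_by_counts,
                                points_per_decade=points_per_decade)
        return {"alpha": fit.alpha}
    fit = fit_exp_mixture(surv, n_components,
                          frame_discretized=frame_discretized,
                          weight_by_counts=weight_by_counts)
    out = {f"tau_{i}": float(v) for i, v in enumerate(fit.taus)}
    out.update({f"f_{i}": float(v) for i, v in enumerate(fit.fractions)})
    if n_components == 2:
        out.update(tau_long=float(fit.taus[0]), tau_short=float(fit.taus[1]),
                   f_long=float(fit.fractions[0]))
    return out


def bootstrap_ci(durations, dt: float, *, family: str = "power_law",
                 n_components: int = 2, k_bleach: float = 0.0,
                 min_events: int = 30, n_boot: int = 1000, seed: int = 0,
                 level: float = 0.95, frame_discretized: bool = False,
                 weight_by_counts: bool = True,
                 points_per_decade: int | None = None) -> dict:
    """Nonparametric bootstrap CIs for dwell-model parameters.

    Durations are resampled with replacement; the full pipeline
    (survival -> truncate -> bleach-correct -> fit) is re-run per
    replicate and percentile intervals are reported.  Survival points are
    strongly dependent, so resampling the underlying durations — not the
    curve — is the honest error model.
    """
    durations = np.asarray(durations, dtype=float)
    rng = np.random.default_rng(seed)
    kw = dict(k_bleach=k_bleach, min_events=min_events, family=family,
              n_components=n_components, frame_discretized=frame_discretized,
              weight_by_counts=weight_by_counts,
              points_per_decade=points_per_decade)
    point = _dwell_point_estimates(durations, dt, **kw)
    reps: dict[str, list[float]] = {k: [] for k in point}
    n = durations.size
    for _ in range(n_boot):
        sample = durations[rng.integers(0, n, size=n)]
        try:
            est = _dwell_point_estimates(sample, dt, **kw)
        except (ValueError, RuntimeError):
            continue
        for key in reps:
            reps[key].append(est[key])
    q = 100 * np.array([(1 - level) / 2, 1 - (1 - level) / 2])
    ci = {k: tuple(np.percentile(v, q)) if v else (np.nan, np.nan)
          for k, v in reps.items()}
    return {"point": point, "ci": ci, "n_boot_ok": len(next(iter(reps.values())))}
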