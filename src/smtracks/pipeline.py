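"""End-to-end analysis pipelines tying the stages together.

Each run takes a config mapping (YAML-compatible), executes
detect -> link -> filter -> analyse for its regime, writes artifacts
under an output directory and returns a :class:`RunReport` from which the
run is reproducible (config + seed -> identical outputs).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dwell as dw
from . import io as sio
from . import mobility as mob
from . import rics as ri
from . import tracking as trk
from .core import MovieStack, TrajectorySet

__all__ = ["RunReport", "run_fast_smt", "run_slow_smt", "run_rics"]

# Defaults marked "protocol" mirror the standard published acquisition and
# filtering settings for these assays; the rest are package choices.
DEFAULTS = {
    "fast": {
        "frame_interval": 0.02, "pixel_size": 0.1,  # protocol
        "max_disp": 0.8, "max_gap": 0,
        "filter": {"min_length": 8, "max_length": 1000,
                   "max_travel": 5.0},  # protocol
    },
    "slow": {
        "frame_interval": 0.5, "pixel_size": 0.1,  # protocol
        "max_disp": 0.45, "max_gap": 1,
        "d_max": 0.1,  # protocol
        "min_events": 30,  # protocol
    },
    "rics": {
        "window": 10,  # protocol
        "pixel_dwell": 12.5e-6, "line_time": 4.313e-3,
        "pixel_size": 0.041,  # protocol
        "w0": 0.25, "wz": 1.5, "fit_radius": [32, 8],
    },
}


@dataclass
class RunReport:
    """Provenance of a pipeline run: stage counts, parameters, metrics."""

    regime: str
    seed: int | None
    config: dict
    stages: list[dict] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)

    def add_stage(self, name: str, n_in: int, n_out: int, **params) -> None:
        self.stages.append({"stage": name, "n_in": n_in, "n_out": n_out,
                            "params": params})

    def to_json(self, path) -> None:
        def clean(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))
        Path(path).write_text(json.dumps(
            {"regime": self.regime, "seed": self.seed, "config": self.config,
             "stages": self.stages, "metrics": self.metrics},
            indent=2, default=clean))


def _merged(regime: str, cfg: dict) -> dict:
    out = json.loads(json.dumps(DEFAULTS[regime]))  # deep copy
    for k, v in (cfg or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _load_tracks(cfg: dict, regime: str) -> TrajectorySet:
    """Movie input -> detect+link; pre-tracked CSV input bypasses detection."""
    dt, ps = cfg["frame_interval"], cfg["pixel_size"]
    if dt is None or ps is None:
        raise ValueError("frame_interval and pixel_size calibration required")
    if cfg.get("tracks_csv"):
        return sio.read_tracks_csv(cfg["tracks_csv"], dt, ps, regime)
    if cfg.get("trajectories") is not None:  # in-memory TrajectorySet
        return cfg["trajectories"]
    movie = cfg.get("movie")
    if movie is None and cfg.get("movie_tiff"):
        movie = sio.read_movie(cfg["movie_tiff"], ps, dt)
    if movie is None:
        raise ValueError("no input: supply movie, movie_tiff or tracks_csv")
    if movie.frames.size == 0 or np.ptp(movie.frames) == 0:
        raise ValueError("movie is empty or constant; nothing to detect")
    locs = trk.detect_stack(movie, trk.DetectionParams(
        **cfg.get("detection", {})))
    return trk.link_trajectories(locs, cfg["max_disp"], cfg["max_gap"],
                                 dt, ps, regime)


def run_fast_smt(cfg: dict, out_dir=None, seed: int | None = None) -> RunReport:
    """Fast-regime pipeline: detect, link, filter, mobility summary."""
    cfg = _merged("fast", cfg)
    report = RunReport("fast", seed, {k: v for k, v in cfg.items()
                                      if not hasattr(v, "frames") and k != "trajectories"})
    ts = _load_tracks(cfg, "fast")
    report.add_stage("tracks", len(ts), len(ts))
    fcfg = trk.FilterConfig(**cfg["filter"], d_max_slow=0.1)
    filtered = trk.filter_fast_tracks(ts, fcfg)
    report.add_stage("filter_fast", len(ts), len(filtered),
                     **cfg["filter"])
    mcfg = mob.MobilityConfig(**cfg.get("mobility", {}))
    summ = mob.summarize_mobility(filtered, mcfg)
    report.metrics = {
        "n_tracks": summ.n_tracks,
        "n_excluded": summ.n_excluded,
        "mobile_fraction": summ.mobile_fraction,
        "mobile_immobile_ratio": summ.mobile_immobile_ratio,
        "auc_um2_s": summ.auc,
        "hist_edges": summ.hist_edges,
        "hist_freq": summ.hist_freq,
        "ensemble_msd_lags_s": summ.ensemble_msd.lags,
        "ensemble_msd_um2": summ.ensemble_msd.msd,
    }
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sio.write_tracks_csv(out / "tracks_filtered.csv", filtered)
        report.to_json(out / "fast_smt_report.json")
        from .plots import plot_mobility_histogram
        ax = plot_mobility_histogram(summ.hist_edges, summ.hist_freq,
                                     mcfg.mobile_threshold_log10)
        ax.figure.savefig(out / "mobility_histogram.png", dpi=120)
    return report


def run_slow_smt(cfg: dict, out_dir=None, seed: int | None = None) -> RunReport:
    """Slow-regime pipeline: survival, truncation, bleach correction,
    mixture/power-law fits and BIC model selection.

    Bleaching is calibrated from control durations (``control_durations``
    or ``control_tracks_csv``) or taken from an explicit ``k_bleach``;
    with correction enabled one of these is mandatory.
    """
    cfg = _merged("slow", cfg)
    report = RunReport("slow", seed, {k: v for k, v in cfg.items()
                                      if isinstance(v, (int, float, str, bool, list, dict))
                                      and k not in ("control_durations",)})
    dt = cfg["frame_interval"]

    if cfg.get("durations") is not None:
        durations = np.asarray(cfg["durations"], dtype=float)
    else:
        ts = _load_tracks(cfg, "slow")
        report.add_stage("tracks", len(ts), len(ts))
        filtered = trk.filter_slow_tracks(
            ts, trk.FilterConfig(d_max_slow=cfg["d_max"]))
        report.add_stage("filter_slow", len(ts), len(filtered),
                         d_max=cfg["d_max"])
        durations = filtered.durations()
        if out_dir:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            sio.write_tracks_csv(Path(out_dir) / "tracks_filtered.csv", filtered)

    correct = cfg.get("bleach_correction", True)
    k_bleach = cfg.get("k_bleach")
    if correct and k_bleach is None:
        ctrl = cfg.get("control_durations")
        if ctrl is None and cfg.get("control_tracks_csv"):
            cts = sio.read_tracks_csv(cfg["control_tracks_csv"], dt,
                                      cfg["pixel_size"], "slow")
            ctrl = cts.durations()
        if ctrl is None:
            raise ValueError("bleach correction enabled but no bleach source "
                             "(control durations or k_bleach) given")
        ctrl_surv = dw.truncate_low_counts(
            dw.build_survival(np.asarray(ctrl, dtype=float), dt),
            cfg["min_events"])
        cal = dw.calibrate_bleach(ctrl_surv, frame_discretized=True)
        k_bleach = cal.k_bleach
        report.metrics["bleach_calibration"] = {
            "k_bleach": cal.k_bleach, "n_components": cal.n_components,
            "bics": cal.bics}
    elif not correct:
        k_bleach = 0.0

    surv = dw.truncate_low_counts(dw.build_survival(durations, dt),
                                  cfg["min_events"])
    if k_bleach:
        surv = dw.bleach_correct(surv, k_bleach)
    report.add_stage("survival", int(len(durations)), len(surv),
                     min_events=cfg["min_events"], k_bleach=k_bleach)

    fd = cfg.get("frame_discretized", True)
    fits = [dw.fit_exp_mixture(surv, 2, frame_discretized=fd),
            dw.fit_exp_mixture(surv, 3, frame_discretized=fd)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fits.append(dw.fit_power_law(
            surv, frame_discretized=fd,
            points_per_decade=cfg.get("points_per_decade")))
    # Family selection defaults to duration-level MLE BIC: survival points
    # are cumulative (correlated), so curve-SSE BIC over-rewards the more
    # flexible model; the multinomial likelihood of the durations is
    # consistent.
    if cfg.get("selection_mode", "mle") == "mle":
        sel_fits = [dw.fit_exp_mixture_mle(durations, dt, 2, k_bleach or 0.0),
                    dw.fit_exp_mixture_mle(durations, dt, 3, k_bleach or 0.0),
                    dw.fit_power_law_mle(durations, dt, k_bleach or 0.0)]
    else:
        sel_fits = fits
    best, table = dw.select_model(sel_fits)
    best = fits[sel_fits.index(best)] if sel_fits is not fits else best
    table = table.astype(object).where(table.notna(), None)
    tau_long, tau_short, f_long = dw.summarize_dwell(fits[0])
    report.metrics.update({
        "k_bleach": k_bleach,
        "selected_family": best.family,
        "selected_n_params": best.n_params,
        "delta_bic": table.to_dict("records"),
        "biexp": {"tau_long": tau_long, "tau_short": tau_short,
                  "f_long": f_long, "bic": fits[0].bic},
        "power_law": {"alpha": fits[2].alpha, "bic": fits[2].bic},
        "n_durations": int(len(durations)),
    })
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savetxt(out / "survival.csv",
                   np.column_stack([surv.times, surv.survival,
                                    surv.events_remaining]),
                   delimiter=",", header="time_s,survival,events", comments="")
        table.to_csv(out / "model_selection.csv", index=False)
        report.to_json(out / "slow_smt_report.json")
        from .plots import plot_survival
        ax = plot_survival(surv, fits=[fits[0], fits[2]],
                           labels=["biexponential", "power law"])
        ax.figure.savefig(out / "survival_fits.png", dpi=120)
    return report


def run_rics(cfg: dict, out_dir=None, seed: int | None = None) -> RunReport:
    """RICS pipeline: moving-average subtraction, ACF, one-component fit."""
    cfg = _merged("rics", cfg)
    report = RunReport("rics", seed, {k: v for k, v in cfg.items()
                                      if isinstance(v, (int, float, str, bool, list))})
    movie = cfg.get("movie")
    if movie is None and cfg.get("movie_tiff"):
        movie = sio.read_movie(cfg["movie_tiff"], cfg["pixel_size"], 1.0)
    if movie is None:
        raise ValueError("no raster stack supplied")
    for key in ("pixel_dwell", "line_time"):
        if cfg.get(key) is None:
            raise ValueError(f"missing scan timing {key!r}")
    if cfg["window"] > movie.n_frames:
        raise ValueError("moving-average window exceeds frame count")
    detrended = ri.moving_average_subtract(movie, cfg["window"])
    acf = ri.compute_acf(detrended, cfg["pixel_dwell"], cfg["line_time"])
    fit = ri.fit_one_component(acf, cfg["w0"], cfg["wz"],
                               tuple(cfg["fit_radius"]))
    report.add_stage("acf", movie.n_frames, 1, window=cfg["window"])
    report.metrics = {"D_um2_s": fit.d, "N": fit.n_particles,
                      "offset": fit.offset, "converged": fit.converged,
                      "sse": fit.sse}
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savetxt(out / "acf_center.csv",
                   acf.g[acf.zero_lag_index()[0]], delimiter=",")
        report.to_json(out / "rics_report.json")
        if fit.converged:
            from .plots import plot_acf_fit
            plot_acf_fit(acf, fit).savefig(out / "acf_fit.png", dpi=120)
    return report
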