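"""Ground-truth validation studies.

Each function simulates a study with the package's synthetic generator at
fixed, documented conditions, runs the corresponding analysis pipeline and
returns the recovered quantities together with the truth they should
match.  They are the backbone of the acceptance suite and are also
convenient as executable documentation of what the pipeline can and
cannot recover.

All randomness is controlled by a single integer seed; independent
sub-streams are derived with ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import dwell as dw
from . import mobility as mob
from . import rics as ri
from . import tracking as trk
from .simulate import (DwellSpec, RasterScanConfig, TwoStateSimConfig,
                       render_movie, simulate_dwell_durations,
                       simulate_raster_scan, simulate_two_state_tracks)

__all__ = [
    "threshold_conversion",
    "mobility_recovery",
    "dwell_recovery",
    "power_law_recovery",
    "bic_family_selection",
    "rics_recovery",
    "tracking_fidelity",
]

# Slow-SMT study conditions: 500-ms frames, 2e4 dwell events, bleaching at
# 0.02/s, 30-event tail truncation.
SLOW_DT = 0.5
N_DWELL = 20_000
K_BLEACH = 0.02
MIN_EVENTS = 30

# H2B-like bleach-calibration control: two fast transient components plus
# a stably bound pool whose intrinsic residence (1 h) is far slower than
# bleaching, so the smallest fitted rate reads out the dye bleach rate.
H2B_SPEC = DwellSpec.exp_mixture((0.5, 0.3, 0.2), (1.0, 10.0, 3600.0))

# Two-population dwell model: 20% specific binding at 40 s, 80%
# nonspecific at 3 s.
BIEXP_SPEC = DwellSpec.exp_mixture((0.2, 0.8), (40.0, 3.0))

# Scale-free binding: survival exponent 0.7 between 0.5 s and an upper
# cutoff far beyond the deepest measurable time point, so the sampled
# tail is a pure power law over the fitted window.
PLAW_SPEC = DwellSpec.power_law(0.7, 0.5, 1e6)

TRIEXP_SPEC = DwellSpec.exp_mixture((0.3, 0.4, 0.3), (100.0, 5.0, 0.5))


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(c.generate_state(1)[0] % (2 ** 31))
            for c in np.random.SeedSequence(seed).spawn(n)]


def threshold_conversion(threshold_log10: float = -1.45) -> float:
    """Linear-scale diffusion cutoff implied by the log10 threshold."""
    return 10.0 ** threshold_log10


def mobility_recovery(seed: int = 0, n_molecules: int = 2000) -> dict:
    """Two-state mobility study: 60% free at 3.5, 40% bound at 0.003 um^2/s.

    20-ms frames; photobleaching at 3.3/s keeps mean track length ~15
    frames; the standard fast-regime filters (length 8..1000, travel
    <= 5 um) are applied before classification at log10 D = -1.45.
    """
    cfg = TwoStateSimConfig(d_free=3.5, d_bound=0.003, k_bind=0.0,
                            k_unbind=0.0, p_free0=0.6, frame_interval=0.02,
                            n_frames=1000, n_molecules=n_molecules,
                            fov=(20.0, 20.0), bleach_rate=3.3, seed=seed)
    ts, _ = simulate_two_state_tracks(cfg)
    filtered = trk.filter_fast_tracks(ts, trk.FilterConfig())
    mcfg = mob.MobilityConfig()
    ds = mob._track_ds(filtered, mcfg)
    frac, ratio = mob.classify_mobile_immobile(ds, cfg=mcfg)
    edges, freq, _, _ = mob.mobility_distribution(ds, mcfg)
    centers = 0.5 * (edges[:-1] + edges[1:])
    thr = mcfg.mobile_threshold_log10
    lo, hi = freq[centers < thr], freq[centers > thr]
    return {
        "true_mobile_fraction": 0.6,
        "mobile_fraction": float(frac),
        "mobile_immobile_ratio": float(ratio),
        "immobile_mode_log10d": float(centers[centers < thr][np.argmax(lo)]),
        "mobile_mode_log10d": float(centers[centers > thr][np.argmax(hi)]),
        "n_tracks": int(len(filtered)),
    }


def _corrected_survival(durations, k_bleach):
    surv = dw.truncate_low_counts(dw.build_survival(durations, SLOW_DT),
                                  MIN_EVENTS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return dw.bleach_correct(surv, k_bleach)


def dwell_recovery(seed: int = 0, n: int = N_DWELL) -> dict:
    """Biexponential dwell recovery under bleaching with H2B calibration.

    Simulates 2e4 durations from (tau_long, tau_short, f_long) =
    (40 s, 3 s, 0.2) bleached at 0.02/s, calibrates the bleach rate from
    an H2B-like control imaged under the same conditions, corrects, and
    fits the two-component model.
    """
    s_ctrl, s_data = _spawn_seeds(seed, 2)
    ctrl, _ = simulate_dwell_durations(H2B_SPEC, K_BLEACH, SLOW_DT, n,
                                       seed=s_ctrl)
    ctrl_surv = dw.truncate_low_counts(dw.build_survival(ctrl, SLOW_DT),
                                       MIN_EVENTS)
    cal = dw.calibrate_bleach(ctrl_surv, frame_discretized=True)

    data, _ = simulate_dwell_durations(BIEXP_SPEC, K_BLEACH, SLOW_DT, n,
                                       seed=s_data)
    surv = _corrected_survival(data, cal.k_bleach)
    fit = dw.fit_exp_mixture(surv, 2, frame_discretized=True)
    tau_long, tau_short, f_long = dw.summarize_dwell(fit)
    return {
        "true": {"tau_long": 40.0, "tau_short": 3.0, "f_long": 0.2,
                 "k_bleach": K_BLEACH},
        "k_bleach": float(cal.k_bleach),
        "bleach_n_components": cal.n_components,
        "tau_long": tau_long,
        "tau_short": tau_short,
        "f_long": f_long,
        "n": n,
    }


def power_law_recovery(seed: int = 0, n: int = N_DWELL,
                       n_coverage_seeds: int = 20,
                       n_boot: int = 1000) -> dict:
    """Power-law exponent recovery plus bootstrap-CI coverage.

    Each of ``n_coverage_seeds`` replicates draws 2e4 bounded-Pareto
    durations (alpha = 0.7) under bleaching, corrects with the known
    bleach rate and fits the survival power law; the 95% bootstrap CI
    should cover the true exponent in ~95% of replicates.
    """
    alphas, covered = [], 0
    for s in _spawn_seeds(seed, n_coverage_seeds):
        durs, _ = simulate_dwell_durations(PLAW_SPEC, K_BLEACH, SLOW_DT, n,
                                           seed=s)
        out = dw.bootstrap_ci(durs, SLOW_DT, family="power_law",
                              k_bleach=K_BLEACH, min_events=MIN_EVENTS,
                              n_boot=n_boot, seed=s + 1,
                              frame_discretized=True)
        alphas.append(out["point"]["alpha"])
        lo, hi = out["ci"]["alpha"]
        covered += int(lo <= PLAW_SPEC.alpha <= hi)
    return {
        "true_alpha": PLAW_SPEC.alpha,
        "alpha": float(np.mean(alphas)),
        "alpha_sd": float(np.std(alphas)),
        "ci_coverage": covered / n_coverage_seeds,
        "n_seeds": n_coverage_seeds,
        "n": n,
    }


def bic_family_selection(seed: int = 0, n: int = N_DWELL,
                         n_seeds: int = 20) -> dict:
    """BIC family recovery: 2-exp vs 3-exp vs power law, MLE mode.

    Each generative family is simulated ``n_seeds`` times (no bleaching)
    and the three candidate models are compared by duration-level BIC.
    Reports per-family and overall selection accuracy.
    """
    gens = {"exp_mixture_2": BIEXP_SPEC, "exp_mixture_3": TRIEXP_SPEC,
            "power_law": PLAW_SPEC}
    acc = {}
    for offset, (name, spec) in enumerate(gens.items()):
        hits = 0
        for s in _spawn_seeds(seed * 3 + offset, n_seeds):
            durs, _ = simulate_dwell_durations(spec, 0.0, SLOW_DT, n, seed=s)
            fits = [dw.fit_exp_mixture_mle(durs, SLOW_DT, 2),
                    dw.fit_exp_mixture_mle(durs, SLOW_DT, 3),
                    dw.fit_power_law_mle(durs, SLOW_DT)]
            best, _ = dw.select_model(fits)
            if name == "power_law":
                hits += best.family == "power_law"
            else:
                hits += (best.family == "exp_mixture"
                         and best.n_components == int(name[-1]))
        acc[name] = hits / n_seeds
    acc["overall"] = float(np.mean(list(acc.values())))
    acc["n_seeds"] = n_seeds
    return acc


def rics_recovery(seed: int = 0, frame_size: int = 128,
                  n_frames: int = 100) -> dict:
    """RICS diffusion recovery at 1 and 3.6 um^2/s with standard scan
    timings (12.5-us pixel dwell, 4.313-ms line time, 41-nm pixels).

    Planar (2D) particle simulations are analysed with the axial factor
    disabled (wz -> inf); the recovered pair should preserve the ~3.6x
    ratio.
    """
    out = {}
    for key, d, s in (("d_slow", 1.0, 0), ("d_fast", 3.6, 1)):
        cfg = RasterScanConfig(d=d, particle_density=0.5,
                               frame_size=frame_size, n_frames=n_frames,
                               brightness=20.0, seed=_spawn_seeds(seed, 2)[s])
        mv = simulate_raster_scan(cfg)
        det = ri.moving_average_subtract(mv, 10)
        acf = ri.compute_acf(det, cfg.pixel_dwell, cfg.line_time)
        fit = ri.fit_one_component(acf, cfg.w0, np.inf, fit_radius=(32, 8))
        out[key] = float(fit.d)
        out[f"{key}_true"] = d
    out["ratio"] = out["d_fast"] / out["d_slow"]
    return out


def tracking_fidelity(seed: int = 0) -> dict:
    """Detection + linking fidelity on rendered sparse movies.

    Noise-free: ground-truth tracks must be reproduced exactly (same
    count, same frame spans).  At SNR ~10 (peak signal ~10x the
    background shot noise): at least 95% of true consecutive-frame links
    must be recovered.
    """
    cfg = TwoStateSimConfig(d_free=0.05, d_bound=0.05, k_bind=0.0,
                            k_unbind=0.0, p_free0=1.0, n_molecules=8,
                            n_frames=100, fov=(20.0, 20.0),
                            frame_interval=0.02, seed=3)
    ts, _ = simulate_two_state_tracks(cfg)

    # --- noise-free exact recovery
    mv = render_movie(ts, 0.13, 1500, noise_model="none", fov=cfg.fov)
    linked = trk.link_trajectories(trk.detect_stack(mv), 0.5, 0, 0.02, 0.1)
    spans_gt = sorted((int(t.frames[0]), int(t.frames[-1])) for t in ts)
    spans_rc = sorted((int(t.frames[0]), int(t.frames[-1])) for t in linked)
    exact = (len(linked) == len(ts)) and spans_gt == spans_rc

    # --- SNR ~ 10: peak ~100 photons over background 100 (sd 10)
    mv2 = render_movie(ts, 0.13, 1100, background_mean=100.0,
                       noise_model="poisson", seed=seed, fov=cfg.fov)
    linked2 = trk.link_trajectories(trk.detect_stack(mv2), 0.5, 0, 0.02, 0.1)
    gt_pos: dict[int, list] = {}
    for tr in ts:
        for f, (x, y) in zip(tr.frames, tr.xy):
            gt_pos.setdefault(int(f), []).append((tr.track_id, x, y))

    def match(f, x, y, gate=0.3):
        best, bd = None, gate
        for tid, gx, gy in gt_pos.get(int(f), []):
            dd = np.hypot(gx - x, gy - y)
            if dd < bd:
                bd, best = dd, tid
        return best

    gt_links = sum(len(t) - 1 for t in ts)
    recovered = 0
    for tr in linked2:
        for i in range(len(tr) - 1):
            a = match(tr.frames[i], *tr.xy[i])
            b = match(tr.frames[i + 1], *tr.xy[i + 1])
            if a is not None and a == b and tr.frames[i + 1] == tr.frames[i] + 1:
                recovered += 1
    return {
        "exact_track_recovery": bool(exact),
        "n_tracks_true": len(ts),
        "n_tracks_recovered": len(linked),
        "link_recovery_snr10": recovered / gt_links,
    }
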