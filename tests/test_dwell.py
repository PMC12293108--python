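"""Survival construction, truncation, bleach correction and model fits."""

import warnings

import numpy as np
import pytest

from smtracks import (DwellSpec, bleach_correct, bootstrap_ci,
                      build_survival, calibrate_bleach, fit_exp_mixture,
                      fit_exp_mixture_mle, fit_power_law, fit_power_law_mle,
                      select_model, simulate_dwell_durations, summarize_dwell,
                      truncate_low_counts)
from smtracks.dwell import SurvivalDistribution


def brute_force_survival(durations, dt):
    """Independent oracle: direct counting at every multiple of dt."""
    durations = np.asarray(durations, float)
    K = int(round(durations.max() / dt))
    times = dt * np.arange(1, K + 1)
    surv = np.array([(durations >= t - 1e-9).mean() for t in times])
    counts = np.array([(durations >= t - 1e-9).sum() for t in times])
    return times, surv, counts


class TestBuildSurvival:
    def test_printed_example(self):
        dt = 0.5
        s = build_survival(np.array([1, 1, 2, 4]) * dt, dt)
        assert np.allclose(s.times, [0.5, 1.0, 1.5, 2.0])
        assert np.allclose(s.survival, [1.0, 0.5, 0.25, 0.25])
        assert np.array_equal(s.events_remaining, [4, 2, 1, 1])

    def test_all_equal_is_step(self):
        s = build_survival([1.5, 1.5, 1.5], 0.5)
        assert np.allclose(s.survival, [1, 1, 1])
        assert len(s) == 3

    def test_matches_brute_force_counting(self, rng):
        durs = np.ceil(rng.exponential(3.0, 500) / 0.5) * 0.5
        s = build_survival(durs, 0.5)
        times, surv, counts = brute_force_survival(durs, 0.5)
        assert np.allclose(s.times, times)
        assert np.allclose(s.survival, surv)
        assert np.array_equal(s.events_remaining, counts)

    def test_dkw_bound_against_exponential(self):
        durs, _ = simulate_dwell_durations(DwellSpec.single_exp(10.0), 0.0,
                                           0.01, 10_000, seed=8)
        s = build_survival(durs, 0.01)
        # S_emp(k dt) = S_true((k-1) dt) for ceil-discretized durations
        expect = np.exp(-(s.times - 0.01) / 10.0)
        assert np.abs(s.survival - expect).max() < 0.02

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_survival([], 0.5)


class TestTruncateLowCounts:
    def test_all_below_threshold_errors(self):
        s = build_survival(np.full(29, 0.5), 0.5)
        with pytest.raises(ValueError):
            truncate_low_counts(s, 30)

    def test_drops_tail_points(self):
        s = SurvivalDistribution(np.array([0.5, 1.0, 1.5, 2.0]),
                                 np.array([1.0, 0.4, 0.29, 0.05]),
                                 np.array([100, 40, 29, 5]), 100, 0.5)
        out = truncate_low_counts(s, 30)
        assert len(out) == 2
        assert np.array_equal(out.events_remaining, [100, 40])

    def test_zero_threshold_is_identity(self):
        s = build_survival([0.5, 1.0, 1.5], 0.5)
        out = truncate_low_counts(s, 0)
        assert np.allclose(out.survival, s.survival)


class TestBleachCorrect:
    def test_zero_rate_identity(self):
        s = build_survival([0.5, 1.0, 1.0, 2.5], 0.5)
        out = bleach_correct(s, 0.0)
        assert np.allclose(out.survival, s.survival)

    def test_closed_form_exponential(self):
        # S_obs = exp(-(k + kb) t) corrected with kb -> exp(-k t) exactly
        t = 0.5 * np.arange(1, 50)
        k, kb = 0.1, 0.05
        s_obs = np.exp(-(k + kb) * t)
        s = SurvivalDistribution(t, s_obs / s_obs[0],
                                 np.full(t.size, 1000), 1000, 0.5)
        out = bleach_correct(s, kb)
        expect = np.exp(-k * t)
        assert np.allclose(out.survival, expect / expect[0])

    def test_overcorrection_warns(self):
        durs, _ = simulate_dwell_durations(DwellSpec.single_exp(5.0), 0.02,
                                           0.5, 5000, seed=3)
        s = truncate_low_counts(build_survival(durs, 0.5), 30)
        with pytest.warns(UserWarning, match="rising"):
            bleach_correct(s, 0.5)

    def test_negative_rate_rejected(self):
        s = build_survival([0.5, 1.0], 0.5)
        with pytest.raises(ValueError):
            bleach_correct(s, -0.1)


def grid_search_sse(surv, frame_discretized=True):
    """Dense 3-decade tau x f grid oracle for the 2-component fit."""
    from smtracks.dwell import _fit_points
    t, y, w, _ = _fit_points(surv, frame_discretized, True)
    best = np.inf
    for tau1 in np.geomspace(0.5, 500, 40):
        for tau2 in np.geomspace(0.05, 50, 40):
            for f in np.linspace(0.02, 0.98, 25):
                model = f * np.exp(-t / tau1) + (1 - f) * np.exp(-t / tau2)
                sse = np.sum((w * (np.log(model) - y)) ** 2)
                best = min(best, sse)
    return best


class TestExpMixtureFit:
    def test_single_exponential_degenerate_recovery(self):
        durs, _ = simulate_dwell_durations(DwellSpec.single_exp(10.0), 0.0,
                                           0.5, 10_000, seed=5)
        s = truncate_low_counts(build_survival(durs, 0.5), 30)
        fit = fit_exp_mixture(s, 2, frame_discretized=True)
        # nested-model degeneracy: either one fraction vanishes or both
        # taus collapse to ~10
        if min(fit.fractions) > 0.05:
            assert np.allclose(fit.taus, 10.0, rtol=0.15)
        else:
            major = fit.taus[np.argmax(fit.fractions)]
            assert abs(major - 10.0) / 10.0 < 0.15

    def test_biexponential_parameter_recovery(self):
        spec = DwellSpec.exp_mixture((0.2, 0.8), (40.0, 3.0))
        durs, _ = simulate_dwell_durations(spec, 0.0, 0.5, 20_000, seed=6)
        s = truncate_low_counts(build_survival(durs, 0.5), 30)
        fit = fit_exp_mixture(s, 2, frame_discretized=True)
        tau_long, tau_short, f_long = summarize_dwell(fit)
        assert abs(tau_long - 40.0) / 40.0 < 0.15
        assert abs(f_long - 0.2) < 0.05
        assert abs(tau_short - 3.0) / 3.0 < 0.15

    def test_beats_dense_grid_search_oracle(self):
        durs = np.array([1, 1, 1, 1, 2, 2, 3, 4, 5, 6, 8, 8, 10, 13, 17,
                         21, 30, 44]) * 0.5
        s = build_survival(durs, 0.5)
        fit = fit_exp_mixture(s, 2, frame_discretized=True)
        assert fit.sse <= grid_search_sse(s) + 1e-9

    def test_too_few_points_rejected(self):
        s = build_survival([0.5, 1.0, 1.0], 0.5)
        with pytest.raises(ValueError):
            fit_exp_mixture(s, 2)


class TestPowerLawFit:
    def test_exact_power_law_recovered(self):
        t = 0.5 * np.arange(1, 200)
        s_vals = (t / t[0]) ** -0.5
        s = SurvivalDistribution(t, s_vals, np.full(t.size, 10_000), 10_000,
                                 0.5)
        fit = fit_power_law(s, weight_by_counts=False)
        assert abs(fit.alpha - 0.5) < 1e-9
        assert abs(fit.amplitude - 1.0) < 1e-9

    def test_alpha_recovery_after_bleach_correction(self):
        spec = DwellSpec.power_law(0.7, 0.5, 1e6)
        durs, _ = simulate_dwell_durations(spec, 0.02, 0.5, 20_000, seed=7)
        s = truncate_low_counts(build_survival(durs, 0.5), 30)
        s = bleach_correct(s, 0.02)
        fit = fit_power_law(s, frame_discretized=True)
        assert abs(fit.alpha - 0.7) < 0.05

    def test_exponential_data_prefers_biexponential(self):
        durs, _ = simulate_dwell_durations(DwellSpec.single_exp(5.0), 0.0,
                                           0.5, 20_000, seed=9)
        s = truncate_low_counts(build_survival(durs, 0.5), 30)
        pl = fit_power_law(s, frame_discretized=True)
        bi = fit_exp_mixture(s, 2, frame_discretized=True)
        assert bi.bic < pl.bic


class TestCalibrateBleach:
    def test_pure_exponential_control(self):
        durs, _ = simulate_dwell_durations(DwellSpec.single_exp(100.0), 0.0,
                                           0.5, 20_000, seed=10)
        s = truncate_low_counts(build_survival(durs, 0.5), 30)
        cal = calibrate_bleach(s, frame_discretized=True)
        assert abs(cal.k_bleach - 0.01) / 0.01 < 0.05

    def test_triexponential_control_smallest_rate(self):
        spec = DwellSpec.exp_mixture((0.3, 0.4, 0.3), (100.0, 5.0, 0.5))
        durs, _ = simulate_dwell_durations(spec, 0.0, 0.5, 50_000, seed=11)
        s = truncate_low_counts(build_survival(durs, 0.5), 30)
        cal = calibrate_bleach(s, frame_discretized=True)
        assert cal.n_components == 3
        assert abs(cal.k_bleach - 0.01) / 0.01 < 0.15


class TestModelSelection:
    def test_equal_sse_prefers_fewer_parameters(self):
        from smtracks.dwell import ExpMixtureFit, _bic
        m = 100
        f2 = ExpMixtureFit(2, np.array([0.5, 0.5]), np.array([10.0, 1.0]),
                           sse=1.0, bic=_bic(1.0, m, 3), n_points=m,
                           converged=True)
        f3 = ExpMixtureFit(3, np.array([0.4, 0.3, 0.3]),
                           np.array([10.0, 1.0, 0.1]), sse=1.0,
                           bic=_bic(1.0, m, 5), n_points=m, converged=True)
        best, table = select_model([f2, f3])
        assert best is f2
        assert table["delta_bic"].min() == 0.0

    def test_mixed_domains_rejected(self):
        from smtracks.dwell import ExpMixtureFit
        a = ExpMixtureFit(2, np.array([0.5, 0.5]), np.array([10.0, 1.0]),
                          1.0, 0.0, 100, True)
        b = ExpMixtureFit(2, np.array([0.5, 0.5]), np.array([10.0, 1.0]),
                          1.0, 0.0, 90, True)
        with pytest.raises(ValueError):
            select_model([a, b])

    @pytest.mark.parametrize("family,spec", [
        ("exp_mixture_2", DwellSpec.exp_mixture((0.2, 0.8), (40.0, 3.0))),
        ("exp_mixture_3", DwellSpec.exp_mixture((0.3, 0.4, 0.3),
                                                (100.0, 5.0, 0.5))),
        ("power_law", DwellSpec.power_law(0.7, 0.5, 1e6)),
    ])
    def test_mle_bic_recovers_generative_family(self, family, spec):
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            durs, _ = simulate_dwell_durations(spec, 0.0, 0.5, 20_000,
                                               seed=200 + seed)
            fits = [fit_exp_mixture_mle(durs, 0.5, 2),
                    fit_exp_mixture_mle(durs, 0.5, 3),
                    fit_power_law_mle(durs, 0.5)]
            best, _ = select_model(fits)
            want = {"exp_mixture_2": (2, "exp_mixture"),
                    "exp_mixture_3": (3, "exp_mixture"),
                    "power_law": (None, "power_law")}[family]
            if best.family == want[1] and (want[0] is None
                                           or best.n_components == want[0]):
                hits += 1
        assert hits >= n_seeds - 1


class TestSummarizeDwell:
    def test_component_ordering(self):
        from smtracks.dwell import ExpMixtureFit
        fit = ExpMixtureFit(2, np.array([0.2, 0.8]), np.array([40.0, 3.0]),
                            0.0, 0.0, 10, True)
        assert summarize_dwell(fit) == (40.0, 3.0, 0.2)

    def test_degenerate_taus_warn(self):
        from smtracks.dwell import ExpMixtureFit
        fit = ExpMixtureFit(2, np.array([0.5, 0.5]), np.array([10.0, 9.5]),
                            0.0, 0.0, 10, True)
        with pytest.warns(UserWarning, match="degenerate"):
            summarize_dwell(fit)


class TestBootstrap:
    def test_power_law_ci_brackets_point_estimate(self):
        spec = DwellSpec.power_law(0.7, 0.5, 1e6)
        durs, _ = simulate_dwell_durations(spec, 0.0, 0.5, 5000, seed=13)
        out = bootstrap_ci(durs, 0.5, family="power_law", n_boot=100,
                           seed=1, frame_discretized=True)
        lo, hi = out["ci"]["alpha"]
        assert lo < out["point"]["alpha"] < hi
        assert hi - lo < 0.3
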