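"""Generator correctness: known-truth checks against closed forms."""

import numpy as np
import pytest
from scipy import stats

from smtracks import (DwellSpec, MovieStack, RasterScanConfig,
                      TwoStateSimConfig, render_movie,
                      simulate_dwell_durations, simulate_raster_scan,
                      simulate_two_state_tracks)


class TestTwoStateTracks:
    def test_zero_diffusion_positions_constant(self):
        cfg = TwoStateSimConfig(d_free=0.0, d_bound=0.0, n_molecules=10,
                                n_frames=50, seed=0)
        ts, _ = simulate_two_state_tracks(cfg)
        for tr in ts:
            assert np.allclose(tr.xy, tr.xy[0])

    def test_brownian_step_variance_matches_2_d_dt(self):
        # all-free population: per-axis displacement variance = 2 D dt
        d, dt = 3.5, 0.02
        cfg = TwoStateSimConfig(d_free=d, k_bind=0.0, p_free0=1.0,
                                frame_interval=dt, n_frames=1001,
                                n_molecules=120, fov=(400.0, 400.0), seed=3)
        ts, _ = simulate_two_state_tracks(cfg)
        steps = np.concatenate([np.diff(tr.xy, axis=0) for tr in ts])
        n = steps.size  # both axes pooled; >= 1e5 steps
        assert n >= 2e5
        var = steps.ravel().var()
        expect = 2 * d * dt
        se = expect * np.sqrt(2.0 / n)  # SE of a Gaussian variance estimate
        assert abs(var - expect) < 3 * se

    def test_absorbing_bound_state_dwell_equals_lifetime(self):
        cfg = TwoStateSimConfig(k_bind=0.0, k_unbind=0.0, p_free0=0.0,
                                bleach_rate=0.5, frame_interval=0.02,
                                n_frames=200, n_molecules=50, seed=4)
        ts, truth = simulate_two_state_tracks(cfg)
        for tr, durs in zip(ts, truth.bound_durations):
            assert len(durs) == 1
            assert abs(durs[0] - tr.duration(0.02)) <= 0.02 + 1e-12

    def test_seed_determinism(self):
        cfg = TwoStateSimConfig(n_molecules=20, n_frames=50, bleach_rate=1.0,
                                seed=9)
        a, _ = simulate_two_state_tracks(cfg)
        b, _ = simulate_two_state_tracks(cfg)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.frames, tb.frames)
            assert np.array_equal(ta.xy, tb.xy)

    def test_bound_run_lengths_match_dwell_spec_ks(self):
        # interior (uncensored) bound runs of an exponential spec are iid
        tau = 2.0
        cfg = TwoStateSimConfig(k_bind=5.0, k_unbind=1 / tau, p_free0=0.5,
                                frame_interval=0.02, n_frames=30000,
                                n_molecules=40, bleach_rate=0.0, seed=14)
        _, truth = simulate_two_state_tracks(cfg)
        runs = truth.all_bound_durations(complete_only=True)
        assert runs.size >= 1e4
        p = stats.kstest(runs, "expon", args=(0, tau)).pvalue
        assert p > 0.01

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TwoStateSimConfig(d_free=-1.0)
        with pytest.raises(ValueError):
            TwoStateSimConfig(frame_interval=0.0)
        with pytest.raises(ValueError):
            TwoStateSimConfig(d_free=np.nan)


class TestDwellDurations:
    def test_exponential_mean_recovered(self):
        d, _ = simulate_dwell_durations(DwellSpec.single_exp(10.0), 0.0,
                                        0.01, 10_000, seed=1)
        se = 10.0 / np.sqrt(10_000)
        assert abs(d.mean() - 10.0) < 3 * se + 0.01  # +dt for ceil rounding

    def test_competing_exponentials_sum_rate(self):
        # dwell rate 0.1 + bleach rate 0.1 -> observed mean 5 s
        d, bleached = simulate_dwell_durations(DwellSpec.single_exp(10.0),
                                               0.1, 0.01, 20_000, seed=2)
        assert abs(d.mean() - 5.0) < 3 * 5.0 / np.sqrt(20_000) + 0.01
        # competing identical rates: bleach wins about half the time
        assert abs(bleached.mean() - 0.5) < 0.02

    def test_power_law_sampler_log_survival_slope(self):
        # inverse-CDF oracle: slope of log S vs log t is -alpha well
        # below the upper cutoff
        alpha, t_min, t_max = 0.7, 0.5, 500.0
        spec = DwellSpec.power_law(alpha, t_min, t_max)
        rng = np.random.default_rng(5)
        t = spec.sample(200_000, rng)
        grid = np.geomspace(t_min, t_max / 10, 12)
        s = np.array([(t >= g).mean() for g in grid])
        slope = np.polyfit(np.log(grid), np.log(s), 1)[0]
        # analytic bounded-Pareto survival on the same grid: the sampler
        # must match its own generative form, whose slope approximates
        # -alpha below the upper cutoff
        s_true = (grid ** -alpha - t_max ** -alpha) / (
            t_min ** -alpha - t_max ** -alpha)
        slope_true = np.polyfit(np.log(grid), np.log(s_true), 1)[0]
        assert abs(slope - slope_true) < 0.02
        assert abs(-slope - alpha) < 0.08

    def test_durations_are_frame_multiples(self):
        d, _ = simulate_dwell_durations(DwellSpec.single_exp(1.0), 0.0, 0.5,
                                        500, seed=3)
        assert np.allclose(d / 0.5, np.round(d / 0.5))
        assert d.min() >= 0.5

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_dwell_durations(DwellSpec.single_exp(1.0), 0.0, 0.5, 0)
        with pytest.raises(ValueError):
            DwellSpec.exp_mixture((0.5, 0.6), (1.0, 2.0))
        with pytest.raises(ValueError):
            DwellSpec.power_law(0.7, 5.0, 1.0)


class TestRenderMovie:
    def _one_emitter_ts(self, x=1.03, y=0.87):
        from tests.conftest import make_set, make_track
        tr = make_track(np.tile([[x, y]], (5, 1)))
        return make_set([tr])

    def test_zero_photons_pure_background(self):
        mv = render_movie(self._one_emitter_ts(), psf_sigma=0.13,
                          photons_per_frame=0, background_mean=7.0,
                          noise_model="none", fov=(2.0, 2.0))
        assert np.allclose(mv.frames, 7.0)

    def test_argmax_at_emitter_pixel(self):
        mv = render_movie(self._one_emitter_ts(1.05, 0.85), psf_sigma=0.13,
                          photons_per_frame=100, noise_model="none",
                          fov=(2.0, 2.0))
        for f in mv.frames:
            iy, ix = np.unravel_index(np.argmax(f), f.shape)
            assert ix == int(1.05 / 0.1) and iy == int(0.85 / 0.1)

    def test_centroid_matches_subpixel_truth(self):
        x, y = 1.033, 0.869
        mv = render_movie(self._one_emitter_ts(x, y), psf_sigma=0.13,
                          photons_per_frame=1000, noise_model="none",
                          fov=(2.0, 2.0))
        f = mv.frames[0]
        yy, xx = np.mgrid[0:f.shape[0], 0:f.shape[1]]
        cx = (f * xx).sum() / f.sum()
        cy = (f * yy).sum() / f.sum()
        assert abs(cx - (x / 0.1 - 0.5)) < 0.05
        assert abs(cy - (y / 0.1 - 0.5)) < 0.05

    def test_bad_psf_rejected(self):
        with pytest.raises(ValueError):
            render_movie(self._one_emitter_ts(), psf_sigma=0.0,
                         photons_per_frame=10)


class TestRasterScan:
    def test_frozen_particles_identical_frames(self):
        cfg = RasterScanConfig(d=0.0, particle_density=1.0, frame_size=32,
                               n_frames=5, shot_noise=False, seed=6)
        mv = simulate_raster_scan(cfg)
        for f in mv.frames[1:]:
            assert np.allclose(f, mv.frames[0])

    def test_single_static_particle_is_beam_profile(self):
        cfg = RasterScanConfig(d=0.0, particle_density=0.0, frame_size=32,
                               n_frames=1, shot_noise=False, seed=0)
        mv = simulate_raster_scan(cfg)
        assert np.allclose(mv.frames, 0.0)  # density 0 -> empty stack
        # now place one particle by brute force through density + seed search
        cfg2 = RasterScanConfig(d=0.0, particle_density=1 / (32 * 0.041) ** 2,
                                frame_size=32, n_frames=1, shot_noise=False,
                                brightness=10.0, seed=0)
        mv2 = simulate_raster_scan(cfg2)
        assert mv2.frames.max() > 0  # one particle expected at this density
        # the profile along the peak row must be Gaussian with waist w0:
        # log I vs (x - centroid)^2 is linear with slope -2 / w0^2
        f = mv2.frames[0]
        iy, ix = np.unravel_index(np.argmax(f), f.shape)
        row = np.roll(f[iy], 16 - ix)  # periodic field: center the peak
        xs = (np.arange(32) - 16) * 0.041
        sel = row > 1e-3 * row.max()
        cx = (row[sel] * xs[sel]).sum() / row[sel].sum()
        slope = np.polyfit((xs[sel] - cx) ** 2, np.log(row[sel]), 1)[0]
        assert abs(slope - (-2 / cfg2.w0 ** 2)) < 0.05 * (2 / cfg2.w0 ** 2)

    def test_seed_determinism(self):
        cfg = RasterScanConfig(frame_size=32, n_frames=3, seed=8)
        assert np.array_equal(simulate_raster_scan(cfg).frames,
                              simulate_raster_scan(cfg).frames)

    def test_invalid_line_time_rejected(self):
        with pytest.raises(ValueError):
            RasterScanConfig(line_time=1e-6, frame_size=256)
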