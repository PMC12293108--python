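# Methods

`smtracks` quantifies how nuclear proteins move and how long they stay
bound to DNA, from two complementary live-cell measurements: single-
molecule tracking (SMT) in two acquisition regimes, and raster image
correlation spectroscopy (RICS). Because raw single-molecule microscopy
data are rarely shareable, every analysis stage is validated against a
built-in synthetic generator with known ground truth; this note records
the models, the numerical choices, and what the validation does and does
not establish.

## Synthetic data model

**Two-state trajectories.** Molecules switch between a freely diffusing
state (D_free, default 3.5 um²/s) and a chromatin-bound state (D_bound,
default 0.003 um²/s) by a continuous-time two-state process with rates
k_bind and k_unbind (1/s); bound-state dwells may instead be drawn from
an arbitrary dwell distribution (exponential mixture or bounded power
law). Positions take per-frame Gaussian steps with per-axis variance
2·D·Δt, with the state evaluated at the frame start; boundaries of the
field of view reflect. Photobleaching is an independent exponential
clock (rate `bleach_rate`) that truncates the observation; whether
biological unbinding and bleaching truly compete as independent
exponentials in a given instrument is not knowable from the data, so the
rate is an explicit free parameter rather than a built-in constant.

**Discretization convention.** A dwell of continuous duration t observed
at frame interval Δt is recorded as ceil(t/Δt) frames — a tracker counts
every frame in which the molecule appears — and a track of k frames has
duration k·Δt. A direct consequence used throughout the fitting code:
the empirical survival evaluated at k·Δt equals the continuous-time
survival at (k−1)·Δt.

**Rendering.** Localizations become 2D Gaussian PSFs (σ in um)
integrated exactly over the pixel grid (erf quadrature) with Poisson
background and shot noise; the camera model is Poisson-only (no EMCCD
excess-noise factor), which suffices for validating the estimators.
Motion blur within a frame is not simulated: the slow regime concerns
near-immobile molecules for which blur is negligible, and the fast
regime's loss of rapidly moving molecules is emulated by the detector's
distance gate rather than by rendering streaks.

**Raster scans.** Particles diffuse in a periodic 2D box matching the
scan field; each scan line samples the instantaneous Gaussian
illumination exp(−2r²/w0²) at that line's acquisition time. Particle
motion *within* one line (tens of microseconds) is not resolved: at the
default timings the fast-axis correlation is dominated by the beam
waist (4·D·τ_p·ξ/w0² ≈ 0.02 at the largest fitted lag), so the
approximation is far below the fit's noise floor. The axial dimension is
not simulated (planar specimens); analyses of these simulations set
wz → ∞ in the fit model.

**Power-law sampler.** Bounded Pareto on [t_min, t_max] via inverse CDF,
with survival exponent α (density exponent 1+α). For *track* simulation
t_max defaults to the movie length. For standalone dwell-duration
studies the upper cutoff is placed far beyond the deepest measurable
time point (default study condition t_max = 10⁶ s): the log-log slope of
a bounded Pareto equals −α only well below the cutoff, and an upper
cutoff inside the fitted window would make the slope read-out
systematically steep — the validation isolates the estimator, so the
generator must be scale-free over the window the estimator sees.

## Fast-regime mobility analysis

Per-track MSD is the time average over all overlapping position pairs,
MSD(kΔt) = ⟨|r(i+k) − r(i)|²⟩ — the standard choice that extracts the
most information from short tracks. The per-track diffusion coefficient
comes from an unweighted linear fit MSD(τ) = 4Dτ + b over the first 4
lags; the intercept b absorbs static localization error so it does not
bias D, and 4 points balance bias against variance at the 8-frame
minimum track length. Tracks are filtered on length (8–1000 frames) and
maximum excursion from the origin (≤ 5 um) before analysis.

Mobility summaries per cell: the histogram of log10 D on [−5, 1] with
0.1-decade bins (frequencies normalized to 1; non-positive fitted D are
excluded and counted), the mobile fraction and mobile:immobile ratio at
the threshold log10 D = −1.45 (≈ 0.035 um²/s; both the fraction and the
count ratio are reported since either convention appears in practice),
the ensemble MSD over the first 10 lags at 20-ms spacing, and its
trapezoidal area (AUC, um²·s).

## Slow-regime dwell-time analysis

Track durations from the slow regime (500-ms frames; diffusing molecules
blur out, so surviving tracks are binding events) are compiled into the
empirical survival S(t) = #{durations ≥ t}/n on the frame grid. Time
points with fewer than 30 remaining events are excluded before fitting
(the tail of a survival curve is dominated by counting noise); an
all-points mode (min_events = 0) exists for paired region comparisons
with small track counts. Tracks alive at the movie's end enter as
observed durations, matching how track lengths are compiled in practice;
fits are therefore mildly right-censored at the movie length.

**Photobleach correction.** The dye bleach rate is calibrated by imaging
a stably bound control (histone H2B): its survival is fitted with 2- and
3-component exponential mixtures, BIC selects between them, and the
smallest rate of the winner is taken as k_bleach — valid because the
control's intrinsic residence (hours) is far slower than bleaching.
Correction multiplies the observed survival by exp(k_bleach·(t − t₁))
and renormalizes at the first retained point t₁. Under the ceil
convention this cancels the bleach factor exactly. A corrected curve
that *rises* beyond 3σ of its local counting noise is flagged with a
warning (the calibration likely over-estimates the bleach rate), never
clipped. Whether to correct with the single smallest control component
or the full control curve is ambiguous in practice; the single-rate
reading is implemented (full-curve division can be composed manually
from the same primitives).

**Model fitting.** Two families are always fitted and reported:

* Exponential mixture S(t) = Σ f_i·exp(−t/τ_i), Σf_i = 1, by bounded
  nonlinear least squares on the log-survival curve. Time constants are
  optimized in log space and fractions through a stick-breaking map (the
  simplex constraint holds exactly); a multi-start over a 5-point
  log-spaced τ grid (all combinations per component count) guards
  against local minima.
* Power law S(t) = A·(t/t_ref)^(−α), with α the negative log-log slope
  of the survival — smaller α means heavier tails, i.e. longer-lived
  binding; the dwell-time *density* exponent is 1+α. Fitted by linear
  least squares of log S on log t.

Two numerical defaults matter and are exposed as flags:

* `frame_discretized` (used by the pipeline): models are evaluated at
  t − Δt and the first grid point (identically 1) is dropped, because
  the empirical survival at k·Δt measures the continuous survival at
  (k−1)·Δt. Without this the power-law exponent is biased high by
  +0.04–0.08 at Δt-scale dwell times.
* `weight_by_counts`: residuals are weighted by √(events remaining),
  since var(log S) ≈ 1/counts. This suppresses a Jensen-type bias
  (E log Ŝ < log S) from the noisy 30-event tail that otherwise inflates
  the fitted exponent by several hundredths.

With both defaults, the generator round-trip recovers α = 0.70 ± 0.01 at
n = 2×10⁴ under 0.02/s bleaching.

**Model selection.** Curve fits report
BIC = m·ln(SSE/m) + p·ln(m) over the m fitted points (p = 2k−1 for a
k-component mixture, p = 2 for the power law), with SSE on the same
weighted log-survival scale so families are commensurable. However,
survival points are cumulative counts and strongly correlated: treating
them as m independent Gaussian observations lets a flexible model absorb
correlated noise and systematically over-selects the 3-component
mixture. Family selection therefore defaults to duration-level maximum
likelihood: the exact multinomial likelihood of the frame-discretized
durations (P(k frames) = S((k−1)Δt) − S(kΔt), with a known bleach rate
entering as a competing exponential clock), scored by
BIC = −2·lnL + p·ln(n). This is the classical consistent setting for
BIC; in generator round-trips it re-identifies 2-exponential,
3-exponential and power-law data in ≥ 19/20 seeds each at n = 2×10⁴,
while curve-SSE selection confuses 2- vs 3-exponential data most of the
time. Both modes are available (`selection_mode="mle" | "curve"`).

**Confidence intervals.** Nonparametric bootstrap over the durations
(default 1000 replicates, seeded): each replicate re-runs the whole
pipeline — survival, truncation, bleach correction, fit — and percentile
intervals are reported. Fit-covariance CIs would be anticonservative
because survival points are dependent.

## RICS

A 10-frame centred moving average (truncated at the ends of the series)
is subtracted per pixel and the global mean restored, removing immobile
cell-scale structure and slow bleaching ramps while preserving the mean
the normalization needs. The spatial autocorrelation
G(ξ,ψ) = ⟨δI(x,y)·δI(x+ξ,y+ψ)⟩/⟨I⟩² is computed per frame by FFT
(circular boundary; verified against a brute-force double loop) and
averaged. The one-component free-diffusion model

G(ξ,ψ) = (γ/N)·(1+4Dτ/w0²)⁻¹·(1+4Dτ/wz²)^(−1/2)
         ·exp(−δr²(ξ²+ψ²)/(w0²(1+4Dτ/w0²))) + offset,
τ(ξ,ψ) = τ_p·|ξ| + τ_l·|ψ|

is fitted (D, N, offset free; beam waists are calibration inputs) over
|ξ| ≤ 32, |ψ| ≤ 8 pixels with the shot-noise zero lag excluded. The
fast-axis lags mostly constrain the waist; the line-time lags carry the
diffusion information at the default timings. γ = 0.3536 (3D Gaussian
focal volume); frame-averaged 2D fitting is used (per-frame fitting with
averaging of D is a trivial composition of the same functions).
Generator round-trips at the default scan settings recover D = 1 and
3.6 um²/s within 10–15%, preserving their ratio.

## Detection and linking

Detection: difference-of-Gaussians band-pass, local maxima within a
7-pixel box above a robust (median + 5·MAD) threshold, then a bounded
least-squares 2D Gaussian fit whose centre may move at most 1.5 px from
the initial maximum. Linking: globally greedy nearest-neighbour
assignment per frame pair under a hard distance gate
(fast regime 0.8 um/frame ≈ the gate implied by D ≈ 10 um²/s at 20 ms;
slow regime 0.45 um/frame, a 3σ gate at the 0.1 um²/s slow-regime
bound), with gap closing of 0 (fast) / 1 (slow) frames. At the sparse
densities SMT requires, greedy assignment and full multiple-target
tracing coincide; the quantities analysed downstream (durations,
displacements) do not depend on crowded-scene disambiguation, which is
explicitly out of scope. Slow-regime tracks are additionally filtered by
estimated D ≤ 0.1 um²/s; tracks too short for a D estimate (< 3 frames)
are dropped by default and counted in provenance.

## What the validation shows — and what it does not

The synthetic generator produces idealized data: isotropic free
diffusion, memoryless state switching (or exactly the requested dwell
law), a spatially uniform Gaussian PSF, Poisson-only noise, no drift, no
blinking, no anomalous diffusion, no nuclear-boundary geometry. Passing
round-trips therefore demonstrate that the estimators are correct and
unbiased *under their own model assumptions* at realistic sample sizes —
they do not certify performance on real nuclei, where localization
error, blur, condensate geometry and non-Markovian binding will widen
error bars and can bias dwell-time tails. The bleach-corrected long
dwell times remain lower bounds in practice: events longer than the
movie are right-censored, and the heaviest tail of a power law is never
observable.

## Problem sizes used by the validation studies

Mobility: 2000 molecules, ≈1200 tracks after filters. Dwell studies:
2×10⁴ durations per condition; 20 seeds for coverage/selection rates;
1000 bootstrap replicates. RICS: 128×128 pixels × 100 frames per
condition. Tracking fidelity: 8 emitters × 100 frames, noise-free and at
SNR ≈ 10. These sizes put simulation error well below every tolerance
asserted in the test suite while keeping the whole suite fast.
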