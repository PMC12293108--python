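# smtracks

Single-molecule tracking and fluorescence-fluctuation analysis for
nuclear proteins: how fast they move, and how long they stay bound to
DNA.

Transcription factors imaged live at single-molecule resolution show two
populations — freely diffusing molecules and chromatin-bound ones — and
the bound population's *residence time* on DNA is a key regulatory
quantity. `smtracks` implements the complete analysis chain for both
acquisition regimes of such experiments, plus an independent
fluctuation-based mobility measurement:

* **Fast SMT** (short exposures, e.g. 20 ms): particle detection
  (band-pass + subpixel Gaussian fit), nearest-neighbour linking,
  trajectory filtering, per-track MSD and diffusion coefficients
  (MSD(τ) = 4Dτ + b), log₁₀D mobility histograms, mobile/immobile
  classification at log₁₀D = −1.45 (≈ 0.035 µm²/s), ensemble MSD and its
  AUC.
* **Slow SMT** (long exposures, e.g. 500 ms, where diffusing molecules
  blur away): dwell-time survival distributions S(t) = P(duration ≥ t),
  low-count tail truncation, photobleach correction calibrated from a
  stably bound H2B control (S_corr = S_obs·e^{k_b(t−t₁)}), fits of
  exponential-mixture (S = Σfᵢe^{−t/τᵢ}) and power-law (S ∝ t^{−α})
  binding models, BIC model selection, and bootstrap confidence
  intervals.
* **RICS** (raster image correlation spectroscopy): moving-average
  detrending, FFT spatial autocorrelation, and a one-component diffusion
  fit exploiting the pixel-dwell/line-time structure of the raster scan.
* **Simulation**: a ground-truth generator for two-state (free/bound)
  trajectories with photobleaching, dwell-duration samplers
  (exponential mixtures, bounded power laws), camera rendering, and
  raster-scanned diffusing emitters — every analysis stage above is
  validated against it.

The library is the interface: import it from Python, or use the thin
`smtracks` CLI (`simulate`, `fast-smt`, `slow-smt`, `rics`) for
file-based runs. `examples/` contains one narrative script per
capability.

## Worked example

Recover two-population DNA-binding times from simulated slow-SMT data
(40 s / 3 s dwells, 20% long-lived, bleached at 0.02/s, bleach rate
calibrated from an H2B-like control):

```bash
python examples/03_dwell_time_analysis.py
```

prints

```
calibrated bleach rate : 0.0199 /s  (truth 0.02)
tau_long  : 37.7 s  (truth 40)
tau_short : 2.95 s (truth 3)
f_long    : 0.207   (truth 0.2)
power-law alpha (for comparison): 0.659
BIC-selected family: exp_mixture
```

`tau_long` is the long (specific) DNA residence time, `f_long` the
fraction of binding events in that population; without the bleach
correction the long residence time would be underestimated roughly
two-fold, because bleaching truncates long binding events. The BIC line
reports which binding model — two-population exponential or scale-free
power law — the data themselves favour.

The other examples print, respectively: exact track reconstruction from
rendered movies (`01`), the bimodal mobility histogram and mobile
fraction of a two-state population (`02`), RICS diffusion recovery at
confocal scan timings (`04`), and a paired condensate/nucleoplasm
dwell analysis using region masks (`05`).

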