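"""Slow-regime dwell-time analysis with photobleach correction.

Simulates 2e4 DNA-binding events from a two-population model
(tau_long = 40 s, tau_short = 3 s, 20% long-lived) observed at 500-ms
frames under 0.02/s photobleaching.  The bleach rate is calibrated from
an H2B-like control (a stably bound histone whose apparent unbinding is
bleach-limited), the survival curve is corrected, and biexponential and
power-law models are fitted and compared by BIC.
"""

from smtracks import DwellSpec, run_slow_smt, simulate_dwell_durations

K_BLEACH = 0.02
data, _ = simulate_dwell_durations(
    DwellSpec.exp_mixture((0.2, 0.8), (40.0, 3.0)), K_BLEACH, 0.5, 20_000,
    seed=2)
control, _ = simulate_dwell_durations(
    DwellSpec.exp_mixture((0.5, 0.3, 0.2), (1.0, 10.0, 3600.0)), K_BLEACH,
    0.5, 20_000, seed=3)

report = run_slow_smt({"durations": data, "control_durations": control})
m = report.metrics
print(f"calibrated bleach rate : {m['k_bleach']:.4f} /s  (truth {K_BLEACH})")
print(f"tau_long  : {m['biexp']['tau_long']:.1f} s  (truth 40)")
print(f"tau_short : {m['biexp']['tau_short']:.2f} s (truth 3)")
print(f"f_long    : {m['biexp']['f_long']:.3f}   (truth 0.2)")
print(f"power-law alpha (for comparison): {m['power_law']['alpha']:.3f}")
print(f"BIC-selected family: {m['selected_family']}")
# The long dwell time is the biologically decisive number: without the
# bleach correction it would read ~22 s instead of ~40 s, because
# bleaching truncates long binding events.
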