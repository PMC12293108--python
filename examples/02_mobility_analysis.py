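"""Fast-regime mobility analysis of a simulated two-state population.

60% of molecules diffuse freely at 3.5 um^2/s, 40% are chromatin-bound at
0.003 um^2/s — mimicking a nuclear transcription factor imaged at 20-ms
exposures.  The analysis recovers a bimodal log10-D histogram, the mobile
fraction, the mobile:immobile ratio and the ensemble MSD AUC.
"""

import numpy as np

from smtracks import TwoStateSimConfig, run_fast_smt, simulate_two_state_tracks

cfg = TwoStateSimConfig(d_free=3.5, d_bound=0.003, k_bind=0.0, k_unbind=0.0,
                        p_free0=0.6, frame_interval=0.02, n_frames=1000,
                        n_molecules=1000, fov=(20.0, 20.0), bleach_rate=3.3,
                        seed=1)
ts, _ = simulate_two_state_tracks(cfg)
report = run_fast_smt({"trajectories": ts})

m = report.metrics
print(f"tracks after filters : {m['n_tracks']}")
print(f"mobile fraction      : {m['mobile_fraction']:.3f}  (truth 0.6)")
print(f"mobile:immobile ratio: {m['mobile_immobile_ratio']:.2f}")
print(f"ensemble MSD AUC     : {m['auc_um2_s']:.4f} um^2 s")

edges = np.asarray(m["hist_edges"])
freq = np.asarray(m["hist_freq"])
centers = 0.5 * (edges[:-1] + edges[1:])
print(f"histogram modes      : {centers[np.argmax(freq)]:.2f} (mobile), "
      f"{centers[:30][np.argmax(freq[:30])]:.2f} (immobile) log10 um^2/s")
# The two modes straddle the -1.45 classification threshold; the mobile
# fraction under-counts truth by a few percent because the 5-um travel
# filter trims the fastest tracks.
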