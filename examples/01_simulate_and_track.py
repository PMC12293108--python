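"""Simulate a sparse single-molecule movie and rebuild the tracks from it.

Eight immobile-ish molecules (D = 0.05 um^2/s) are rendered as
diffraction-limited spots, detected frame by frame (band-pass + Gaussian
fit) and re-linked by nearest-neighbour assignment.  With noise-free
rendering the reconstruction should match the ground truth exactly.
"""

import numpy as np

from smtracks import (TwoStateSimConfig, detect_stack, link_trajectories,
                      render_movie, simulate_two_state_tracks)

cfg = TwoStateSimConfig(d_free=0.05, d_bound=0.05, k_bind=0.0, k_unbind=0.0,
                        p_free0=1.0, n_molecules=8, n_frames=60,
                        fov=(20.0, 20.0), frame_interval=0.02, seed=3)
truth_ts, truth = simulate_two_state_tracks(cfg)
movie = render_movie(truth_ts, psf_sigma=0.13, photons_per_frame=1500,
                     noise_model="none", fov=cfg.fov)

locs = detect_stack(movie)
tracks = link_trajectories(locs, max_disp=0.5, frame_interval=0.02,
                           pixel_size=0.1)

print(f"ground truth: {len(truth_ts)} tracks; reconstructed: {len(tracks)}")
err = []
for tr in tracks:
    gt = min(truth_ts.tracks, key=lambda g: np.hypot(*(g.xy[0] - tr.xy[0])))
    err.append(np.abs(gt.xy - tr.xy).max())
print(f"worst localization error: {max(err) * 1000:.3g} nm")
# Without noise the symmetric Gaussian fit lands on the true centre to
# sub-nanometre precision; with photon noise the floor rises to tens of
# nanometres (see the SNR-10 study in the test suite).
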