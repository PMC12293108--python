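import numpy as np
import pytest

from smtracks import (DwellSpec, TwoStateSimConfig, simulate_two_state_tracks)
from smtracks.core import Track, TrajectorySet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def immobile_mix_ts():
    """60/40 free/bound static-state population, fast regime."""
    cfg = TwoStateSimConfig(d_free=3.5, d_bound=0.003, k_bind=0.0,
                            k_unbind=0.0, p_free0=0.6, frame_interval=0.02,
                            n_frames=400, n_molecules=400, fov=(20.0, 20.0),
                            bleach_rate=3.3, seed=7)
    ts, truth = simulate_two_state_tracks(cfg)
    return ts, truth


def make_track(xy, track_id=0, frames=None):
    xy = np.asarray(xy, dtype=float)
    if frames is None:
        frames = np.arange(len(xy))
    return Track(track_id, frames, xy)


def make_set(tracks, dt=0.02, ps=0.1, regime="fast"):
    return TrajectorySet(list(tracks), dt, ps, regime)


@pytest.fixture
def toy_track():
    """5-point track with hand-written coordinates for exhaustive oracles."""
    return make_track([[0.0, 0.0], [0.1, 0.05], [0.25, 0.1],
                       [0.2, 0.3], [0.4, 0.35]])
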