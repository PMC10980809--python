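import numpy as np
import pytest

from hydromig.tracks import Track, TrackSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_trackset(rng, n_tracks=4, n_samples=20, ndim=2, dt=1.0, scale=3.0):
    """Random-walk tracks for oracle comparisons (not APRW-distributed)."""
    tracks = []
    for i in range(n_tracks):
        steps = rng.normal(0.0, scale, size=(n_samples - 1, ndim))
        pos = np.vstack([np.zeros(ndim), np.cumsum(steps, axis=0)])
        pos += rng.uniform(-50, 50, ndim)
        tracks.append(Track(f"t{i}", np.arange(n_samples) * dt, pos))
    return TrackSet(tuple(tracks), dt=dt)


@pytest.fixture
def small_trackset(rng):
    return random_trackset(rng)
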