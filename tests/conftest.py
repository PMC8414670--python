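import numpy as np
import pytest

from sptconfine.core import AcquisitionMeta, TrackDataset, Trajectory

TAU = 0.01376


@pytest.fixture(scope="session")
def meta() -> AcquisitionMeta:
    return AcquisitionMeta()


def make_track(xy, track_id="t0", frames=None, cell_id=None) -> Trajectory:
    xy = np.asarray(xy, dtype=float)
    if frames is None:
        frames = np.arange(len(xy))
    return Trajectory(track_id, np.asarray(frames), xy, cell_id)


def brownian_track(rng, D, n_steps, tau=TAU, noise=0.0, start=(0.0, 0.0),
                   track_id="t0") -> Trajectory:
    """Free (unbounded) Brownian track: per-axis step SD sqrt(2 D tau)."""
    steps = rng.standard_normal((n_steps, 2)) * np.sqrt(2.0 * D * tau)
    xy = np.vstack([np.asarray(start), np.asarray(start) + np.cumsum(steps, axis=0)])
    if noise:
        xy = xy + rng.standard_normal(xy.shape) * noise
    return make_track(xy, track_id=track_id)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def small_brownian_dataset(rng, meta) -> TrackDataset:
    """200 free Brownian tracks, D = 0.5, 12 steps, no noise."""
    tracks = [brownian_track(rng, 0.5, 12, track_id=f"t{i:03d}") for i in range(200)]
    return TrackDataset(tracks, meta)
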