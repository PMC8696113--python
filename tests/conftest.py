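import numpy as np
import pytest

from tred.io import Trajectory, TrajectoryDataset
from tred.preprocess import PreprocessConfig, preprocess_dataset
from tred.synthetic import MotionSpec, simulate_track


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_brownian_track(D, n_steps, rng, track_id="t0", label=None, sigma_loc=0.0):
    return simulate_track(
        MotionSpec("brownian", D=D, sigma_loc=sigma_loc), n_steps, rng,
        track_id=track_id, label=label,
    )


@pytest.fixture
def labeled_dataset(rng):
    """Small 2-class Brownian dataset with distinct diffusivities."""
    tracks = []
    for label, D in [("slow", 0.01), ("fast", 0.1)]:
        for i in range(8):
            tracks.append(
                make_brownian_track(D, 150, rng, track_id=f"{label}-{i}", label=label)
            )
    return TrajectoryDataset(tracks, provenance="fixture")


def make_separable_positions(rng, n_per_class=40, length=64, scales=(0.05, 0.5)):
    """(n, length, 2) cumulative-sum position arrays, one step scale per class."""
    Xs, ys = [], []
    for ci, s in enumerate(scales):
        steps = rng.normal(0, s, size=(n_per_class, length - 1, 2))
        pos = np.concatenate(
            [np.zeros((n_per_class, 1, 2)), np.cumsum(steps, axis=1)], axis=1
        )
        Xs.append(pos)
        ys.extend([f"class{ci}" for _ in range(n_per_class)])
    return np.concatenate(Xs), np.array(ys)


TINY_NET = dict(base_channels=8, max_epochs=12, early_stop_patience=12,
                learning_rate=0.01, dropout_rate=0.1, batch_size=16)


@pytest.fixture
def tiny_net_kwargs():
    """Narrow, fast network configuration for engine-behaviour tests."""
    return dict(TINY_NET)
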