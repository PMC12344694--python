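import numpy as np
import pytest

from dynpot.model import EGNN, ModelConfig
from dynpot.synthetic import GeneratorSpec, default_system, generate_dataset
from dynpot.trajectory import build_subsequence_dataset


@pytest.fixture(scope="session")
def toy_system():
    return default_system()


@pytest.fixture(scope="session")
def small_trajectories(toy_system):
    """Two short reference trajectories of the toy system (61 frames each)."""
    spec = GeneratorSpec(n_trajectories=2, n_steps=60, seed=42)
    return generate_dataset(toy_system, spec)


@pytest.fixture(scope="session")
def train_samples(small_trajectories):
    samples = []
    for t, traj in enumerate(small_trajectories):
        samples.extend(build_subsequence_dataset(traj, s_max=5, cutoff=5.0, traj_id=t))
    return samples


@pytest.fixture(scope="session")
def val_samples(small_trajectories):
    samples = []
    for t, traj in enumerate(small_trajectories):
        samples.extend(
            build_subsequence_dataset(traj, s_max=10, cutoff=5.0, traj_id=t, stride=7)
        )
    return samples


@pytest.fixture()
def tiny_model():
    cfg = ModelConfig(
        species=("H", "Pd"), node_dim=8, edge_dim=6, num_layers=2,
        cutoff=5.0, rff_seed=3, init_seed=4,
    )
    return EGNN.initialise(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
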