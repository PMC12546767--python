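import numpy as np
import pytest

from pocketrank import (
    WorldConfig,
    generate_world,
    label_activity,
    sample_assays,
)
from pocketrank.model import PocketLigandModel, TrainConfig


@pytest.fixture(scope="session")
def world():
    """Reference noiseless synthetic world shared by read-only tests."""
    return generate_world(
        WorldConfig(n_pockets=12, n_ligands=250, latent_dim=8, noise_sd=0.0, seed=5)
    )


@pytest.fixture(scope="session")
def collection(world):
    return sample_assays(world, 24, 15, seed=5)


@pytest.fixture(scope="session")
def labels(collection):
    return label_activity(collection)


@pytest.fixture(scope="session")
def ref_results(collection, labels):
    """A trained reference model (read-only; do not mutate params)."""
    model = PocketLigandModel(collection, d=8, hidden=None, labels=labels)
    return model.fit(TrainConfig(seed=5, steps=300))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
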