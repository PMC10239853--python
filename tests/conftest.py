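"""Shared fixtures: tiny synthetic datasets and cheap trained networks.

Everything is generated programmatically and seeded; the expensive
full-geometry end-to-end run lives in test_acceptance.py behind a
session-scoped fixture so it is computed once.
"""

import pytest

from deepeeg.architecture import build_scaled_architecture
from deepeeg.data import CaseDefinition
from deepeeg.experiments import separable_binary_case, separable_binary_dataset
from deepeeg.network import TrainingConfig, train_network

TEST_SEED = 7


@pytest.fixture(scope="session")
def tiny_dataset():
    """Two separable classes, 20 epochs each, 512-sample epochs."""
    return separable_binary_dataset(seed=TEST_SEED, n_per_class=20, epoch_length=512)


@pytest.fixture(scope="session")
def tiny_case() -> CaseDefinition:
    return separable_binary_case()


@pytest.fixture(scope="session")
def tiny_arch():
    return build_scaled_architecture(512, 2)


@pytest.fixture(scope="session")
def tiny_network(tiny_arch, tiny_dataset):
    """A briefly trained scaled network on the tiny dataset."""
    config = TrainingConfig(epochs=3, batch_size=16, seed=TEST_SEED)
    net, history = train_network(tiny_arch, tiny_dataset, config)
    return net, history
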