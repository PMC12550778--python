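import numpy as np
import pytest

from sharkfuse.synth import SyntheticConfig, generate_dataset, split_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny easy CT-profile dataset shared by model-level tests."""
    cfg = SyntheticConfig(n_per_class=30, image_size=(32, 32), seed=7)
    return split_dataset(generate_dataset(cfg), (0.6, 0.2, 0.2), seed=7)


def random_probability_matrix(rng, n, k=3, concentration=1.0):
    """Dirichlet rows: a generic valid probability matrix."""
    return rng.dirichlet(np.full(k, concentration), size=n)
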