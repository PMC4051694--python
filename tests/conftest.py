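import numpy as np
import pytest

from dielprot import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_proteins=30, mean_protein_length=200, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
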