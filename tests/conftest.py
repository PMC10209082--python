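import numpy as np
import pytest

from subplastid import (
    GeneratorConfig,
    extract_presence,
    generate_dataset,
    generate_signal_msa,
)


@pytest.fixture(scope="session")
def small_dataset():
    """8 classes x 8 records; big enough to train on, small enough to be fast."""
    return generate_dataset(GeneratorConfig(n_per_class=8, seed=11))


@pytest.fixture(scope="session")
def small_features(small_dataset):
    return extract_presence(small_dataset)


@pytest.fixture(scope="session")
def signal_msas():
    return {
        "Sec": generate_signal_msa("Sec", 30, 101),
        "Tat": generate_signal_msa("Tat", 30, 202),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
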