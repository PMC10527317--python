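import numpy as np
import pytest

from copdfusion.synthetic import default_spec, generate_paired_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small complementary paired dataset shared across tests."""
    spec = default_spec(60, seed=7, volume_shape=(8, 16, 16))
    return generate_paired_dataset(spec)
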