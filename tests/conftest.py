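import numpy as np
import pytest

from leafspec import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded draw at the default study conditions (90 samples, Fe)."""
    return generate_dataset(SyntheticConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
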