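import numpy as np
import pytest

from enhancerdiff.synthetic import SyntheticConfig, generate, small_test_config


def small_config(seed: int = 5) -> SyntheticConfig:
    """Scaled-down synthetic dataset for unit tests: same geometry and
    noise model as the default conditions, fewer elements."""
    return small_test_config(seed)


@pytest.fixture(scope="session")
def small_dataset():
    return generate(small_config())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
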