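import numpy as np
import pytest

from neuromodml import synthetic as syn


@pytest.fixture(scope="session")
def spec():
    """Reduced-scale cohort spec shared across tests."""
    return syn.small_spec(seed=7)


@pytest.fixture(scope="session")
def rseeg(spec):
    return syn.generate_rseeg(spec, 123)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
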