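import numpy as np
import pytest

from persistlin import EMGParams, fixture_suite, hct116_config


@pytest.fixture(scope="session")
def fixtures():
    """The hand-checkable toy tables."""
    return fixture_suite(seed=42)


@pytest.fixture(scope="session")
def std_emg():
    """A typical pre-drug IMT parameterization (mean ~20 h)."""
    return EMGParams(10.0, 2.0, 0.1)


@pytest.fixture(scope="session")
def hct116_cfg():
    return hct116_config()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
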