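import numpy as np
import pytest

import trophicweb as tw


@pytest.fixture(scope="session")
def fixture_web():
    """The hand-computable 6-species web."""
    return tw.fixture_web()


@pytest.fixture(scope="session")
def fixture_coeffs():
    """Round-number coefficients (SEs zero) for hand calculation."""
    return tw.fixture_coefficients()


@pytest.fixture(scope="session")
def default_coeffs():
    """The packaged allometric scaling coefficients."""
    return tw.load_coefficients()


@pytest.fixture(scope="session")
def small_synth_web():
    """A 30-species annotated niche-model web (session-cached)."""
    return tw.synthetic_web(tw.SynthConfig(S=30, C=0.1, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
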