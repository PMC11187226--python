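import numpy as np
import pytest

from intronkit import SplicingRateConstants


@pytest.fixture
def control_rates():
    """Uninhibited splicing rate constants (min^-1)."""
    return SplicingRateConstants(0.037, 0.031)


@pytest.fixture
def inhibited_rates():
    """Rate constants at 50 μM inhibitor (min^-1)."""
    return SplicingRateConstants(0.007, 0.001)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
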