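import numpy as np
import pytest

from warfinr import PUBLISHED


@pytest.fixture(scope="session")
def params():
    """The published parameter set."""
    return PUBLISHED


@pytest.fixture()
def rng():
    """Fresh seeded generator per test."""
    return np.random.default_rng(20180813)
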