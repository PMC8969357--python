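import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def wt_gaussian(rng):
    """114 wild-type replicates of a Gaussian noise feature."""
    return rng.normal(0.0, 1.0, 114)
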