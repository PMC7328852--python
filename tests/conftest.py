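import numpy as np
import pytest

from chemoassay import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noiseless_oct_params():
    """Exactly renderable phantom: no speckle, no column roughness."""
    return sd.OCTPhantomParams(speckle_sd=0.0, roughness_um=0.0, seed=0)


@pytest.fixture
def quiet_oct_params():
    return sd.OCTPhantomParams(seed=0)
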