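import numpy as np
import pytest

from cbh import SimParams


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(1234))


@pytest.fixture
def params():
    """A mid-range parameter set exercising every lifecycle branch."""
    return SimParams(phi=0.3, tau=0.9, zeta=0.5, lam=1.0,
                     init_s=0.4, init_v=0.3, init_l=0.5, generations=0)
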