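import numpy as np
import pytest

from rheodipole import FishState, ModelParams, NondimParams


@pytest.fixture
def params():
    """Dimensional parameters with rho = 0.1 and moderate shear."""
    return ModelParams(h=1.0, U0=0.5, eps=0.2, v0=1.0, r0=0.1, l=0.25, K=2.0)


@pytest.fixture
def params_noflow():
    """Quiescent background: dipole + walls only."""
    return ModelParams(h=1.0, U0=0.0, eps=0.0, v0=1.0, r0=0.1, l=0.25, K=0.0)


@pytest.fixture
def fish():
    return FishState(0.3, 0.37, 0.7)


@pytest.fixture
def nd20():
    """Nondimensional parameters with beta = 20 (three upstream equilibria)."""
    return NondimParams(rho=0.1, alpha=0.1, kappa=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
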