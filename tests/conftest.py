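import numpy as np
import pytest

from locsim import Medium


@pytest.fixture
def water() -> Medium:
    """Room-temperature water, the suspension medium of both devices."""
    return Medium(eta=8.9e-4, T=300.0, eps_m=80.0, sigma_m=0.0, rho_f=1000.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
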