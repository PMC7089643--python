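import numpy as np
import pytest

from seasonpop import ResourceParams, SpeciesParams


@pytest.fixture(scope="session")
def sp50():
    """Default species: adult mass 50 g, symmetric stages (q = 1)."""
    return SpeciesParams.from_adult_mass(50.0)


@pytest.fixture(scope="session")
def rp():
    return ResourceParams()


@pytest.fixture(scope="session")
def nu_max(sp50):
    """Maximum juvenile net production at q = 1 (saturating resource)."""
    return sp50.sigma * sp50.rates.M - sp50.rates.T


@pytest.fixture
def rng():
    return np.random.default_rng(20160901)
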