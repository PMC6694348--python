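import numpy as np
import pytest

from marrowdose import (CoefficientTables, DecayData, PhantomConfig,
                        generate_phantom)


@pytest.fixture(scope="session")
def phantom():
    """Default synthetic patient (seed 1) shared across tests."""
    return generate_phantom(PhantomConfig(), seed=1)


@pytest.fixture(scope="session")
def material(phantom):
    return phantom.material_map()


@pytest.fixture(scope="session")
def skeletal(phantom):
    return phantom.skeletal_map()


@pytest.fixture(scope="session")
def tables():
    return CoefficientTables.load()


@pytest.fixture(scope="session")
def lu177():
    return DecayData.lu177()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
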