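import numpy as np
import pytest

from nscmigrate.phantoms import (PhantomSpec, make_phantom_with_tissue,
                                 make_scenario)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def straight_phantom():
    """Small verified 2-D straight-tract phantom with its tissue field."""
    spec = PhantomSpec(shape=(160, 160))
    vol, tissue = make_phantom_with_tissue(spec, np.random.default_rng(7))
    return spec, vol, tissue


@pytest.fixture(scope="session")
def grey_phantom():
    """Uniform grey 2-D phantom (no white matter anywhere)."""
    spec = PhantomSpec(shape=(128, 128), kind="uniform_grey")
    vol, tissue = make_phantom_with_tissue(spec, np.random.default_rng(7))
    return spec, vol, tissue


@pytest.fixture(scope="session")
def near_scenario():
    return make_scenario("near_tumor", dim=2, rng=np.random.default_rng(11))


@pytest.fixture(scope="session")
def no_tumor_scenario():
    return make_scenario("no_tumor", dim=2, rng=np.random.default_rng(11))
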