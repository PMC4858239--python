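import numpy as np
import pytest

from paleodiff import HabitabilityParams, compute_habitability
from paleodiff.synthetic import make_fixture_suite


@pytest.fixture(scope="session")
def suite():
    return make_fixture_suite(rng_seed=0)


@pytest.fixture(scope="session")
def params():
    return HabitabilityParams()


@pytest.fixture(scope="session")
def valley(suite):
    """Scored two-valley island with its two seeds."""
    fx = suite["two_valley_island"]
    return fx, compute_habitability(fx.elev, fx.water)


@pytest.fixture(scope="session")
def strip(suite):
    """Uniform 1x21 land strip with two symmetric seeds."""
    fx = suite["strip"]
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fields = compute_habitability(fx.elev, fx.water)
    return fx, fields
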