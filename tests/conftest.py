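import warnings

import numpy as np
import pytest

from renalnet.morphometry import ExtrapolationWarning, load_profile


@pytest.fixture(autouse=True)
def _quiet_extrapolation():
    # samplers are routinely queried just below the fitted diameter range
    # (near D_stop); that is expected and logged, not a test failure signal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        yield


@pytest.fixture(scope="session")
def default_dists():
    return load_profile("default")


@pytest.fixture(scope="session")
def degenerate_dists():
    return load_profile("degenerate")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
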