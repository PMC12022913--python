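import warnings

import numpy as np
import pytest

from hemesam.synth import (DEFAULT_PACKING_PER_CM2, reference_hopping_params,
                           reference_tunneling_params)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Generator/fit warnings about censored V=0 points are expected."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="all scans censored")
        yield


@pytest.fixture
def hop_params():
    return reference_hopping_params()


@pytest.fixture
def tun_params():
    return reference_tunneling_params()


@pytest.fixture
def packing():
    return DEFAULT_PACKING_PER_CM2


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
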