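import warnings

import numpy as np
import pytest

from startint import Cln3KineticParams, IntegratorParams


@pytest.fixture(autouse=True)
def _quiet_censoring_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*censored.*")
        yield


@pytest.fixture
def params():
    """Default Cln3 kinetics (the canonical simulation conditions)."""
    return Cln3KineticParams()


@pytest.fixture
def integrator():
    """Default Whi5 integrator parameters."""
    return IntegratorParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
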