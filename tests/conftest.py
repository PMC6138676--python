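import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def wildtype_dsc_model():
    """Two-state model at the wild-type Ig transition parameters."""
    from lamindyn.dsc import TwoStateModel

    return TwoStateModel(tm_K=61.9 + 273.15, dh_vh=110.1, dh_cal=110.1)


@pytest.fixture
def mutant_dsc_model():
    """Two-state model at the W514R mutant transition parameters."""
    from lamindyn.dsc import TwoStateModel

    return TwoStateModel(tm_K=50.5 + 273.15, dh_vh=45.6, dh_cal=45.6)
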