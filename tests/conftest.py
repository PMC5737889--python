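import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from exactcells import make_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def zebra():
    """2 x 4 boater-activity x awareness survey, N = 274."""
    return make_fixture("zebra_mussel")


@pytest.fixture
def melanoma():
    """4 x 3 tumor-type x tumor-site table, N = 400."""
    return make_fixture("melanoma")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
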