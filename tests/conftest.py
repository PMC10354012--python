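import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*facilitation.*")
        warnings.filterwarnings("ignore", message=".*inhibition.*")
        yield
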