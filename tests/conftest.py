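import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_candidate_warnings():
    # n_top > survivor count is exercised intentionally in several tests
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="only .* candidates survive")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
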