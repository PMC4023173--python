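import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "splitmeta",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("splitmeta")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
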