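import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from adcr.synthetic import SyntheticCohortSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """A small cohort spec used where image size does not matter."""
    return SyntheticCohortSpec(n_good=3, n_poor=3, volume_shape=(12, 12, 12), seed=7)
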