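import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scheme():
    """Shared blastp-default scoring scheme (warms the JIT once)."""
    from lucifind.align import default_scheme, smith_waterman

    s = default_scheme()
    smith_waterman("MKT", "MKT", s)  # trigger compilation up front
    return s


@pytest.fixture()
def rng():
    return np.random.default_rng(20160112)
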