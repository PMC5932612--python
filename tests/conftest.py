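import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chainmap import align, simulate
from chainmap.types import Thresholds

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_ref():
    """A 4-chromosome ~9 Mb toy reference (label maps only)."""
    _, maps = simulate.simulate_reference(
        7, chrom_len=[3e6, 2e6, 2e6, 2e6], gc=0.41, return_sequences=False
    )
    return maps


@pytest.fixture(scope="session")
def small_index(small_ref):
    return align.ReferenceIndex(small_ref)


@pytest.fixture
def th():
    return Thresholds()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
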