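import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gridtag import enumerate_codebook

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def book():
    """Full usable code set (Hamming >= 3 over ids 1..32767)."""
    return enumerate_codebook(3)


@pytest.fixture(scope="session")
def book_small():
    """Truncated code set for cheap rendering/detection tests."""
    return enumerate_codebook(3, (1, 3000))


@pytest.fixture(scope="session")
def book_h7():
    """High-robustness code set (Hamming >= 7)."""
    return enumerate_codebook(7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
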