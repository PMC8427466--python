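import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom128():
    """Default single-animal phantom at the full acquisition matrix."""
    from hepaflow.phantom import make_phantom

    return make_phantom(matrix=128)


@pytest.fixture(scope="session")
def phantom64():
    """Reduced-matrix phantom for cheaper map-level tests."""
    from hepaflow.phantom import make_phantom

    return make_phantom(matrix=64)


@pytest.fixture(scope="session")
def tis50():
    return 110.0 * np.arange(1, 51)
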