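import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cpcsim import table1_parameters

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return table1_parameters()


@pytest.fixture(scope="session")
def y0():
    return np.array([30000.0, 12300.0, 738.0, 334.0, 10.0])
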