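import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from cscplasticity import ModelParameters, load_scenario

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def normoxia():
    return load_scenario("normoxia")


@pytest.fixture(scope="session")
def hypoxia():
    return load_scenario("hypoxia")


@pytest.fixture
def generic_params():
    """A well-behaved constant-rate parameter set used across modules."""
    return ModelParameters(
        alpha_S=0.4, delta_S=0.1, alpha_D=0.5, delta_D=0.1, k_SD=0.05, k_DS=0.01
    )
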