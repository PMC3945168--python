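import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_progenitor_params():
    from dediffsim import ProgenitorParams

    return ProgenitorParams()


@pytest.fixture(scope="session")
def coarse_progenitor_params():
    """Coarser grid for tests that step the PDE many times."""
    from dediffsim import ProgenitorParams

    return ProgenitorParams(age_step=0.1)
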