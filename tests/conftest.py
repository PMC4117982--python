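import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from axonwave.engine import SimConfig, initialize
from axonwave.morphology import build_axon, discretize
from axonwave.protocols import measure_cv, settle

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def control_cable():
    return discretize(build_axon("control"))


@pytest.fixture(scope="session")
def control_state(control_cable):
    return settle(control_cable)


@pytest.fixture(scope="session")
def control_cv(control_cable, control_state):
    """Headline control conduction-velocity result, shared across tests."""
    return measure_cv(control_cable, state=control_state)


@pytest.fixture(scope="session")
def aoe_cvs():
    """Fully dysmyelinated AOE1/AOE2 conduction velocities."""
    out = {}
    for cond in ("AOE1", "AOE2"):
        cable = discretize(build_axon(cond))
        out[cond] = measure_cv(cable)
    return out
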