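import logging

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# silence the (expected) staggered-gap warnings from simulated ITS data
logging.getLogger("barcodelim.diagnostics").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_scenario():
    from barcodelim.simulate import default_lini_scenario

    return default_lini_scenario()


@pytest.fixture(scope="session")
def default_dataset(default_scenario):
    """One simulated default-scenario dataset (seed 1)."""
    from barcodelim.simulate import generate_dataset

    return generate_dataset(default_scenario, seed=1)
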