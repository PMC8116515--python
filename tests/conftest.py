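import pytest
from hypothesis import HealthCheck, settings

from t2dsim import fixtures as fx
from t2dsim.scenarios import load_preset, run_scenario

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clock():
    return fx.default_clock()


@pytest.fixture(scope="session")
def journey_params():
    """Default journey calibration; treat as read-only (use dataclasses.replace)."""
    return fx.default_parameters()


@pytest.fixture(scope="session")
def cost_params():
    return fx.default_cost_parameters()


@pytest.fixture(scope="session")
def baseline_result(journey_params, cost_params, clock):
    """The no-intervention run on the default 1990-2035 calibration."""
    return run_scenario(
        load_preset("no_intervention"), journey_params, cost_params, clock
    )
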