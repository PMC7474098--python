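import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import demproj as dp

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic input bundle (session-wide, treated as read-only)."""
    return dp.make_synthetic_bundle()


@pytest.fixture(scope="session")
def small_panels(bundle):
    """A small central two-pass run under scenario 0 (both sexes)."""
    scen = dp.ScenarioSpec.from_id(0)
    return dp.run_two_pass(bundle, scen, n_per_cohort=400, seed=11)
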