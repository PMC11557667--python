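import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gazecone as gz

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ctx165() -> gz.GeometryContext:
    """The canonical 165 cm live-looker geometry with a 6.5 cm IPD."""
    return gz.GeometryContext(viewing_distance_cm=165.0, ipd_cm=6.5)


@pytest.fixture(scope="session")
def exp1_design(ctx165) -> gz.StimulusDesign:
    """One-sided exponential design: 5 directions x 25 repetitions."""
    return gz.exponential_stimulus_design(2.5, 4, ctx165, repetitions=25)


@pytest.fixture(scope="session")
def exp2_design() -> gz.StimulusDesign:
    """Two-sided linear design: 11 directions x 35 repetitions."""
    return gz.linear_stimulus_design(3.0, 15.0, repetitions=35)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240509)
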