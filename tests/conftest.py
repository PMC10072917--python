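import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from codiversity import AgeScheme, CauseScheme, transition_scenario

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def causes() -> CauseScheme:
    return CauseScheme.default()


@pytest.fixture(scope="session")
def ages() -> AgeScheme:
    return AgeScheme.gbd_default()


@pytest.fixture(scope="session")
def fine_ages() -> AgeScheme:
    """Single-year grid to an open 110+ interval."""
    return AgeScheme(tuple(float(a) for a in range(0, 111)))


@pytest.fixture(scope="session")
def small_scenario():
    """A small but fully structured transition scenario (2 regions)."""
    return transition_scenario(
        n_regions=2, countries_per_region=2, years=(1990, 1999),
        region_offsets=(10.0, 40.0), seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_scenario):
    from codiversity import generate_panel

    return generate_panel(small_scenario)
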