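import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

import hrvfatigue as hf


@pytest.fixture(scope="session")
def study():
    """Embedded 12-patient summary table as (features, bfi array)."""
    return hf.fixture_features()


@pytest.fixture(scope="session")
def sim_profile():
    return hf.make_profile(5.67, seed=3)


@pytest.fixture(scope="session")
def sim_stream(sim_profile):
    """One simulated 7-day measurement stream (deterministic)."""
    return hf.generate_measurements(sim_profile)
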