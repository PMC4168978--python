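import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def two_locus_valley():
    from recombscape.experiments import make_fixture

    return make_fixture("two_locus_valley")


@pytest.fixture
def additive_L3():
    from recombscape.experiments import make_fixture

    return make_fixture("additive_L3")
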