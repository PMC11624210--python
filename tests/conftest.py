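import pytest

from sjactiv import SimConfig, make_worked_example, simulate_cohort


@pytest.fixture(scope="session")
def worked_example():
    return make_worked_example()


@pytest.fixture(scope="session")
def sim_default():
    """The default synthetic study conditions: 60 Active / 600 Inactive /
    30 Ambiguous samples, 40 true features, threefold effect, seed 17."""
    return simulate_cohort(SimConfig(seed=17))
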