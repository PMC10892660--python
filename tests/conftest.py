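import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pbpkddi import load_compound, load_physiology
from pbpkddi.ddi import Scenario, simulate_ddi
from pbpkddi.engine import DoseEvent

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def saxagliptin():
    return load_compound("saxagliptin")


@pytest.fixture(scope="session")
def nicardipine():
    return load_compound("nicardipine")


@pytest.fixture(scope="session")
def rat_phys():
    return load_physiology("rat", 0.25)


@pytest.fixture(scope="session")
def human_phys():
    return load_physiology("human", 70.0)


@pytest.fixture(scope="session")
def rat_scenario(saxagliptin, nicardipine):
    """The emulated rat DDI study: victim 5 mg/kg + perpetrator 15 mg/kg, oral solutions."""
    return Scenario(
        victim=saxagliptin,
        victim_doses=[DoseEvent("oral", 5.0, per_kg=True)],
        species="rat",
        body_weight_kg=0.25,
        duration_h=24.0,
        perpetrator=nicardipine,
        perpetrator_doses=[DoseEvent("oral", 15.0, per_kg=True)],
    )


@pytest.fixture(scope="session")
def rat_sxg_result(rat_scenario):
    return rat_scenario.simulate_victim_alone()


@pytest.fixture(scope="session")
def rat_ddi_result(rat_scenario):
    return simulate_ddi(rat_scenario, keep_results=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
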