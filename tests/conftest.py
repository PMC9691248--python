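import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ilextract.kinetics import ExtractionSystem, KineticModel
from ilextract.synthetic import ScenarioConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def system():
    """Reference biphasic system: 3 mL serum at 0.125 mg/mL + 0.7 g IL."""
    return ExtractionSystem(v_aq=3.0, q=0.375, il_mass=0.7)


@pytest.fixture
def kinetic_model(system):
    return KineticModel(k1=0.9489, k2=0.010646, system=system)


@pytest.fixture
def scenario():
    return ScenarioConfig(seed=12345)


@pytest.fixture
def rng():
    return np.random.default_rng(20220930)
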