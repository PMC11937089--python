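import numpy as np
import pytest

from drivevigil.synth import EffectConfig, ScenarioConfig, generate_session


@pytest.fixture(scope="session")
def small_scenario() -> ScenarioConfig:
    """Reduced-scale scenario: six 60 s sections."""
    return ScenarioConfig(duration_s=360.0, section_s=60.0, seed=1)


@pytest.fixture(scope="session")
def small_session(small_scenario):
    """One generated Manual-condition session shared across tests."""
    session, truth = generate_session(small_scenario, EffectConfig())
    return session, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
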