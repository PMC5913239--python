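import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glp1pharm import synthetic_data as sd

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel() -> sd.GroundTruthPanel:
    return sd.default_panel()


@pytest.fixture()
def design() -> sd.AssayDesign:
    return sd.AssayDesign()


@pytest.fixture()
def no_noise() -> sd.NoiseModel:
    return sd.NoiseModel(cv=0.0, sd=0.0, seed=0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
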