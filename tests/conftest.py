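import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ckdcost.config import AnalysisConfig
from ckdcost.synthetic import SyntheticConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def acfg() -> AnalysisConfig:
    return AnalysisConfig(seed=0)


@pytest.fixture(scope="session")
def synth_config() -> SyntheticConfig:
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def cohort433(synth_config):
    """Default synthetic cohort: 260 outpatient, 30 inpatient, 143 dialysis."""
    return generate_cohort(synth_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
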