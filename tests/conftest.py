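import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cellcascade import FateProbs, Rates, fate_probs_from_rates

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: published single-positive thymocyte rates (division, death, exit; per day)
SP4_RATES = Rates(lam=0.181, mu=0.040, nu=0.231)
SP8_RATES = Rates(lam=0.085, mu=0.110, nu=0.152)


@pytest.fixture(scope="session")
def sp4() -> FateProbs:
    return fate_probs_from_rates(SP4_RATES)


@pytest.fixture(scope="session")
def sp8() -> FateProbs:
    return fate_probs_from_rates(SP8_RATES)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20231109)
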