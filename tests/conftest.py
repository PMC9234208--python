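import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cloudhealth import CloudConcept1D, InferenceRule

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# study-condition concepts: index state-association cloud and problem-trend
# cloud of the reference community cohort
INDEX_CONCEPT = CloudConcept1D(22.4, 5.043, 0.325)
TREND_CONCEPT = CloudConcept1D(0.325, 0.325, 0.032)


@pytest.fixture
def index_concept() -> CloudConcept1D:
    return INDEX_CONCEPT


@pytest.fixture
def trend_concept() -> CloudConcept1D:
    return TREND_CONCEPT


@pytest.fixture
def rule(index_concept, trend_concept) -> InferenceRule:
    return InferenceRule(antecedent=index_concept, consequent=trend_concept)


@pytest.fixture
def det_rule() -> InferenceRule:
    """The same rule with hyper-entropies forced to zero (deterministic)."""
    return InferenceRule(
        antecedent=CloudConcept1D(22.4, 5.043, 0.0),
        consequent=CloudConcept1D(0.325, 0.325, 0.0),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
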