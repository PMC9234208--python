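"""Seeded synthetic cohorts with known cloud-model structure.

Two generators make the whole pipeline testable without external data:

* :func:`generate_indices` draws continuous mental-health indices from a
  configured normal cloud, so the backward generator and the reasoning
  pipeline can be exercised against known ground truth;
* :func:`generate_responses` emulates item-level questionnaire answers.
  Each respondent carries a latent severity s in [0, 1]; every item is
  drawn Binomial(3, s), so the item mean rises linearly in s and the total
  is Binomial(3 * n_items, s).  A Bernoulli draw decides whether the
  respondent is a screening-positive type, the latent s comes from the
  matching Beta component, and a bounded redraw keeps the realised total
  on the correct side of the screening cutoff — the expected flagged
  fraction therefore equals the configured target exactly.

This is an emulation of survey data, not a psychometric item-response
model: real items are correlated beyond a single latent factor and real
severity is not Beta-distributed.  What the generators guarantee is only
the marginal structure the downstream estimators consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .clouds import CloudConcept1D, SeedLike, as_rng, forward_cloud_1d
from .questionnaire import FLAG_CUTOFF, Instrument, QuestionnaireResponse

__all__ = ["SyntheticCohortConfig", "generate_indices", "generate_responses"]

#: Beta(a, b) latent-severity components for screening-negative and
#: screening-positive respondents.  The negative component keeps item
#: totals almost surely at or below the cutoff, the positive one above it;
#: the bounded redraw enforces the rare exceptions.
_LATENT_NEGATIVE = (2.0, 28.0)
_LATENT_POSITIVE = (6.0, 6.0)

_MAX_ITEM_REDRAWS = 1000

#: Default demographic mix of a community epidemic-prevention workforce.
DEFAULT_DEMOGRAPHIC_MIX: dict[str, dict[str, float]] = {
    "gender": {"female": 0.55, "male": 0.45},
    "age": {"18-30": 0.3, "31-45": 0.4, "46-60": 0.3},
    "marriage": {"married": 0.65, "single": 0.3, "other": 0.05},
    "education": {"secondary": 0.35, "college": 0.45, "graduate": 0.2},
    "occupation": {
        "community_cadre": 0.4,
        "property_worker": 0.25,
        "community_police": 0.15,
        "medical_worker": 0.2,
    },
    "working_hours": {"<=8h": 0.45, "8-12h": 0.4, ">12h": 0.15},
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Configuration of one synthetic cohort.

    Defaults mirror the reference study conditions: a 600-respondent
    community cohort whose index distribution follows the cloud
    C(22.4, 5.043, 0.325), with a 0.4 screening-positive fraction.
    """

    n_respondents: int = 600
    index_concept: CloudConcept1D = field(
        default_factory=lambda: CloudConcept1D(22.4, 5.043, 0.325)
    )
    flagged_fraction_target: float = 0.4
    instrument: Instrument = Instrument.DEPRESSION9
    demographic_mix: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_DEMOGRAPHIC_MIX
    )
    seed: SeedLike = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        if not (0.0 <= self.flagged_fraction_target <= 1.0):
            raise ValueError("flagged_fraction_target must lie in [0, 1]")
        object.__setattr__(self, "instrument", Instrument(self.instrument))
        for fld, mix in self.demographic_mix.items():
            total = sum(mix.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(
                    f"demographic mix for {fld!r} sums to {total}, expected 1"
                )


def generate_indices(config: SyntheticCohortConfig) -> pd.DataFrame:
    """Draw one index drop per respondent from the configured cloud."""
    return forward_cloud_1d(
        config.index_concept, config.n_respondents, rng=as_rng(config.seed)
    )


def _draw_items(
    rng: np.random.Generator, n_items: int, positive: bool
) -> tuple[int, ...]:
    a, b = _LATENT_POSITIVE if positive else _LATENT_NEGATIVE
    for _ in range(_MAX_ITEM_REDRAWS):
        s = rng.beta(a, b)
        items = rng.binomial(3, s, size=n_items)
        total = int(items.sum())
        if (total > FLAG_CUTOFF) == positive:
            return tuple(int(v) for v in items)
    raise RuntimeError(
        "could not realise a total on the configured side of the cutoff"
    )


def generate_responses(config: SyntheticCohortConfig) -> list[QuestionnaireResponse]:
    """Generate item-level responses with the configured flagged fraction."""
    rng = as_rng(config.seed)
    n_items = config.instrument.n_items
    width = max(4, len(str(config.n_respondents)))
    responses = []
    for i in range(config.n_respondents):
        positive = rng.random() < config.flagged_fraction_target
        items = _draw_items(rng, n_items, positive)
        demographics = {
            fld: rng.choice(list(mix.keys()), p=list(mix.values()))
            for fld, mix in config.demographic_mix.items()
        }
        responses.append(
            QuestionnaireResponse(
                respondent_id=f"R{i + 1:0{width}d}",
                instrument=config.instrument,
                items=items,
                demographics=demographics,
            )
        )
    return responses
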