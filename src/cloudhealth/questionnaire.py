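"""Questionnaire scoring for the 9-item depression and 7-item anxiety scales.

Both screening instruments score every item 0-3; the totals run to 27
(depression, 9 items) and 21 (anxiety, 7 items).  A respondent is flagged
as screening positive when the total is strictly greater than 5; severity
bands start at the cutoffs 5/10/15/20 (depression: mild, moderate, severe,
extreme severe) and 5/10/15 (anxiety: mild, moderate, severe).

Note an intentional quirk of the scoring convention: a total of exactly 5
falls in the "mild" band but is *not* flagged, because flagging uses the
strict "> 5" rule while bands use cutoff minima.  The two rules come from
different sentences of the screening protocol and are both kept as stated
rather than silently reconciled.

The module also provides the ratio memberships that feed cloud estimation:
an index (or level) is graded against a positive reference value — the
worst-affected group's mean — as min(value / reference, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "Instrument",
    "Severity",
    "QuestionnaireResponse",
    "SeverityAssessment",
    "MembershipReference",
    "score_response",
    "membership_index",
    "membership_level",
    "cohort_summary",
    "index_from_total",
    "reference_from_worst_stratum",
    "responses_to_frame",
    "frame_to_responses",
]

DEMOGRAPHIC_FIELDS = (
    "gender",
    "age",
    "marriage",
    "education",
    "occupation",
    "working_hours",
)

FLAG_CUTOFF = 5  # screening positive iff total > 5 (strict)


class Instrument(str, Enum):
    DEPRESSION9 = "depression9"
    ANXIETY7 = "anxiety7"

    @property
    def n_items(self) -> int:
        return 9 if self is Instrument.DEPRESSION9 else 7

    @property
    def max_total(self) -> int:
        return 3 * self.n_items


class Severity(str, Enum):
    NONE = "none"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"
    EXTREME_SEVERE = "extreme_severe"


# band minima; the last band runs to the scale maximum
_BANDS = {
    Instrument.DEPRESSION9: [
        (20, Severity.EXTREME_SEVERE),
        (15, Severity.SEVERE),
        (10, Severity.MODERATE),
        (5, Severity.MILD),
        (0, Severity.NONE),
    ],
    Instrument.ANXIETY7: [
        (15, Severity.SEVERE),
        (10, Severity.MODERATE),
        (5, Severity.MILD),
        (0, Severity.NONE),
    ],
}


@dataclass(frozen=True)
class QuestionnaireResponse:
    """One respondent's item scores plus demographics."""

    respondent_id: str
    instrument: Instrument
    items: tuple
    demographics: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        instrument = Instrument(self.instrument)
        object.__setattr__(self, "instrument", instrument)
        items = tuple(self.items)
        if len(items) != instrument.n_items:
            raise ValueError(
                f"{instrument.value} needs {instrument.n_items} items, "
                f"got {len(items)} (respondent {self.respondent_id})"
            )
        for pos, item in enumerate(items, start=1):
            if item not in (0, 1, 2, 3):
                raise ValueError(
                    f"item{pos} must be in 0..3, got {item!r} "
                    f"(respondent {self.respondent_id})"
                )
        object.__setattr__(self, "items", tuple(int(v) for v in items))


@dataclass(frozen=True)
class SeverityAssessment:
    total: int
    flagged: bool
    severity: Severity


def score_response(resp: QuestionnaireResponse) -> SeverityAssessment:
    """Total, screening flag and severity band for one response."""
    total = sum(resp.items)
    for cutoff, severity in _BANDS[resp.instrument]:
        if total >= cutoff:
            break
    return SeverityAssessment(
        total=total, flagged=total > FLAG_CUTOFF, severity=severity
    )


@dataclass(frozen=True)
class MembershipReference:
    """Positive reference value for ratio membership (the worst group's mean)."""

    reference_value: float

    def __post_init__(self) -> None:
        if not (self.reference_value > 0) or not math.isfinite(self.reference_value):
            raise ValueError(
                f"reference_value must be positive and finite, "
                f"got {self.reference_value!r}"
            )


def _ratio_membership(value, ref: MembershipReference, name: str):
    arr = np.asarray(value, dtype=float)
    if (arr < 0).any():
        raise ValueError(f"{name} must be >= 0")
    u = np.minimum(arr / ref.reference_value, 1.0)
    return float(u) if u.ndim == 0 else u


def membership_index(x_i, ref: MembershipReference):
    """Membership of a mental-health index: x/X below the reference, else 1."""
    return _ratio_membership(x_i, ref, "index")


def membership_level(p_i, ref: MembershipReference):
    """Membership of a mental-health level: p/P below the reference, else 1."""
    return _ratio_membership(p_i, ref, "level")


def index_from_total(total, a: float = 1.0, c: float = 0.0):
    """Affine map from questionnaire total to continuous index (default identity)."""
    return a * np.asarray(total, dtype=float) + c


def responses_to_frame(responses: Sequence[QuestionnaireResponse]) -> pd.DataFrame:
    """Serialise to the response CSV dialect.

    Columns: respondent_id, instrument, item1..item9 (item8/item9 empty for
    the 7-item scale), then the demographic fields.
    """
    rows = []
    for r in responses:
        row = {"respondent_id": r.respondent_id, "instrument": r.instrument.value}
        for pos in range(1, 10):
            row[f"item{pos}"] = r.items[pos - 1] if pos <= len(r.items) else pd.NA
        for fld in DEMOGRAPHIC_FIELDS:
            row[fld] = r.demographics.get(fld, pd.NA)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_responses(frame: pd.DataFrame) -> list[QuestionnaireResponse]:
    """Parse the response CSV dialect back into response objects."""
    responses = []
    for _, row in frame.iterrows():
        instrument = Instrument(row["instrument"])
        items = []
        for pos in range(1, instrument.n_items + 1):
            value = row[f"item{pos}"]
            if pd.isna(value):
                raise ValueError(
                    f"item{pos} missing for respondent {row['respondent_id']}"
                )
            items.append(int(value))
        demographics = {
            fld: row[fld]
            for fld in DEMOGRAPHIC_FIELDS
            if fld in frame.columns and not pd.isna(row[fld])
        }
        responses.append(
            QuestionnaireResponse(
                respondent_id=str(row["respondent_id"]),
                instrument=instrument,
                items=tuple(items),
                demographics=demographics,
            )
        )
    return responses


def cohort_summary(
    responses: Sequence[QuestionnaireResponse],
    by: Sequence[str] = DEMOGRAPHIC_FIELDS,
) -> pd.DataFrame:
    """Descriptive cross-tabulation per demographic stratum.

    One row per (demographic, stratum): respondent count, mean total,
    flagged fraction and a count per severity band.
    """
    if not responses:
        raise ValueError("cohort must be non-empty")
    scored = []
    for r in responses:
        a = score_response(r)
        record = {
            "total": a.total,
            "flagged": a.flagged,
            "severity": a.severity.value,
        }
        for fld in by:
            record[fld] = r.demographics.get(fld, "unknown")
        scored.append(record)
    frame = pd.DataFrame(scored)

    blocks = []
    for fld in by:
        grouped = frame.groupby(fld, sort=True)
        block = grouped.agg(
            n=("total", "size"),
            mean_total=("total", "mean"),
            flagged_fraction=("flagged", "mean"),
        )
        for sev in Severity:
            block[f"n_{sev.value}"] = grouped["severity"].agg(
                lambda s, v=sev.value: int((s == v).sum())
            )
        block.insert(0, "stratum", block.index)
        block.insert(0, "demographic", fld)
        blocks.append(block.reset_index(drop=True))
    return pd.concat(blocks, ignore_index=True)


def reference_from_worst_stratum(
    responses: Sequence[QuestionnaireResponse],
    indices: Optional[Union[Sequence[float], Mapping[str, float]]] = None,
    by: str = "occupation",
) -> MembershipReference:
    """Reference value X from the worst-affected stratum's mean index.

    Strata are formed by one demographic field; the stratum with the
    highest mean index (questionnaire totals by default, or the supplied
    per-respondent indices) defines the reference.  Overridable by passing
    an explicit :class:`MembershipReference` wherever one is consumed.
    """
    if not responses:
        raise ValueError("cohort must be non-empty")
    if indices is None:
        values = [float(score_response(r).total) for r in responses]
    elif isinstance(indices, Mapping):
        values = [float(indices[r.respondent_id]) for r in responses]
    else:
        values = [float(v) for v in indices]
        if len(values) != len(responses):
            raise ValueError("indices must match responses one-to-one")
    frame = pd.DataFrame(
        {
            "stratum": [r.demographics.get(by, "unknown") for r in responses],
            "index": values,
        }
    )
    means = frame.groupby("stratum")["index"].mean()
    return MembershipReference(reference_value=float(means.max()))
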