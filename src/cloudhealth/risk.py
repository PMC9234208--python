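"""Exponential risk-utility layer: severity S(w) and risk level R.

The severity of a mental-health problem grows faster than the disorder
level itself, so it is modelled by a convex preference utility

    S(w) = kappa * (exp(gamma * w) - 1),        S'(w) > 0,  S''(w) > 0,

with the scale constant kappa = 0.576 and gamma = 1 by default.  The risk
level of a problem is the probability of the problem times its severity,

    R = P * S(w),

which ranks problems for intervention priority.  Rank order is invariant
to kappa and, when all levels w are equal, to gamma.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SCALE_CONSTANT",
    "MentalProblemRecord",
    "RiskAssessment",
    "severity",
    "risk_level",
    "rank_problems",
    "load_problem_table",
    "risk_report",
]

#: Default scale constant of the preference utility; configuration, never
#: hard-coded at call sites, and rank orders do not depend on it.
SCALE_CONSTANT = 0.576


@dataclass(frozen=True)
class MentalProblemRecord:
    """One problem domain: its probability of occurring and mean index."""

    problem: str
    probability: float
    index: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(
                f"probability must lie in [0, 1], got {self.probability}"
            )


@dataclass(frozen=True)
class RiskAssessment:
    problem: str
    probability: float
    w: float
    gamma: float
    severity: float
    risk: float


def severity(w, gamma: float = 1.0, scale: float = SCALE_CONSTANT):
    """Preference-utility severity S(w) = scale * (e^(gamma w) - 1).

    Strictly increasing and convex in w >= 0; zero iff w = 0.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    arr = np.asarray(w, dtype=float)
    if (arr < 0).any():
        raise ValueError("disorder level w must be >= 0")
    s = scale * (np.exp(gamma * arr) - 1.0)
    return float(s) if s.ndim == 0 else s


def risk_level(
    record: MentalProblemRecord,
    w: float,
    gamma: float = 1.0,
    scale: float = SCALE_CONSTANT,
) -> RiskAssessment:
    """Risk R = P * S(w) for one problem record."""
    s = severity(w, gamma=gamma, scale=scale)
    return RiskAssessment(
        problem=record.problem,
        probability=record.probability,
        w=float(w),
        gamma=float(gamma),
        severity=s,
        risk=record.probability * s,
    )


def rank_problems(
    records: Sequence[MentalProblemRecord],
    w_map: Mapping[str, float],
    gamma: float = 1.0,
    scale: float = SCALE_CONSTANT,
) -> list[RiskAssessment]:
    """Assess every record and sort by risk descending (ties by name)."""
    missing = [r.problem for r in records if r.problem not in w_map]
    if missing:
        raise ValueError(f"no disorder level w supplied for: {missing}")
    assessments = [
        risk_level(r, w_map[r.problem], gamma=gamma, scale=scale) for r in records
    ]
    return sorted(assessments, key=lambda a: (-a.risk, a.problem))


def load_problem_table() -> list[MentalProblemRecord]:
    """The bundled eight-problem reference table (probability and index)."""
    with resources.files("cloudhealth.data").joinpath("problem_table.csv").open() as fh:
        frame = pd.read_csv(fh)
    return [
        MentalProblemRecord(
            problem=row["problem"],
            probability=float(row["probability"]),
            index=float(row["index"]),
        )
        for _, row in frame.iterrows()
    ]


def risk_report(assessments: Sequence[RiskAssessment]) -> pd.DataFrame:
    """Tabulate assessments as `problem,probability,w,severity,risk`."""
    return pd.DataFrame(
        [
            {
                "problem": a.problem,
                "probability": a.probability,
                "w": a.w,
                "severity": a.severity,
                "risk": a.risk,
            }
            for a in assessments
        ]
    )
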