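"""Conditional cloud generators and rule-based uncertainty reasoning.

A prediction rule "IF index-state THEN problem-trend" couples two concepts:
an antecedent cloud C_A over the mental-health-index universe and a
consequent cloud C_B over the problem-level universe.  The X-conditional
generator activates the antecedent — a specific input x receives a random
certainty degree u — and the Y-conditional generator emits an output drop
(b, u) under the control of that same u, so the uncertainty of the input
concept is transmitted to the output concept unchanged.

The output formula has two branches: on the *rising* edge (x below the
antecedent expectation) b = ExB - En'B * sqrt(-2 ln u); on the *falling*
edge b = ExB + En'B * sqrt(-2 ln u).  At x = ExA both collapse to
b = ExB (classified as falling for determinism).

:func:`predict_mental_health` chains the pieces into the five-step
prediction pipeline: estimate C_A (and optionally C_B) from historical
drops with the reverse generator, then run many single-rule inferences per
current index and aggregate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .backward import ReverseCloudModel
from .clouds import CloudConcept1D, SeedLike, as_rng, draw_en_prime

__all__ = [
    "InferenceRule",
    "InferenceResult",
    "PredictionConfig",
    "PredictionReport",
    "activate_antecedent",
    "emit_consequent",
    "single_rule_infer",
    "multi_rule_infer",
    "predict_mental_health",
]


@dataclass(frozen=True)
class InferenceRule:
    """One "IF index-state THEN problem-trend" rule.

    ``antecedent`` is the state-association cloud over the index universe;
    ``consequent`` the problem-trend cloud, typically over [0, 1].
    """

    antecedent: CloudConcept1D
    consequent: CloudConcept1D

    def to_dict(self) -> dict:
        return {
            "antecedent": self.antecedent.to_dict(),
            "consequent": self.consequent.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InferenceRule":
        return cls(
            antecedent=CloudConcept1D.from_dict(d["antecedent"]),
            consequent=CloudConcept1D.from_dict(d["consequent"]),
        )

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "InferenceRule":
        text = str(source)
        if text.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(json.loads(Path(source).read_text()))


@dataclass(frozen=True)
class InferenceResult:
    """One output cloud drop of a rule inference.

    ``u`` is the certainty transferred from antecedent to consequent;
    ``en_a_prime``/``en_b_prime`` are the realised entropy draws.
    """

    b: float
    u: float
    edge: str  # "rising" | "falling"
    en_a_prime: float
    en_b_prime: float


@dataclass(frozen=True)
class PredictionConfig:
    """Knobs of the prediction pipeline.

    ``n_drops`` inferences are aggregated per input (600 by default, enough
    to pin the mean output to a few per-mille); the emit-until-positive loop
    is bounded by ``max_iterations`` so the pipeline can never spin forever.
    """

    n_drops: int = 600
    max_iterations: int = 10
    seed: SeedLike = None

    def __post_init__(self) -> None:
        if self.n_drops < 1:
            raise ValueError("n_drops must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def activate_antecedent(
    x: float, rule: InferenceRule, rng: SeedLike = None
) -> tuple[float, float]:
    """X-conditional generator: certainty of input x under the antecedent.

    Draws En'A ~ Normal(EnA, HeA) and returns
    (u = exp(-(x - ExA)^2 / (2 En'A^2)), En'A).
    """
    rng = as_rng(rng)
    concept = rule.antecedent
    if concept.is_degenerate:
        if x == concept.ex:
            return 1.0, 0.0
        raise ValueError(
            "degenerate antecedent (en = he = 0) only activates at x = ex"
        )
    en_a_prime = float(draw_en_prime(concept.en, concept.he, 1, rng)[0])
    u = math.exp(-((x - concept.ex) ** 2) / (2.0 * en_a_prime**2))
    return u, en_a_prime


def emit_consequent(
    u: float,
    x: float,
    rule: InferenceRule,
    rng: SeedLike = None,
    en_a_prime: float = float("nan"),
) -> InferenceResult:
    """Y-conditional generator: emit the output drop for certainty u.

    Draws En'B ~ Normal(EnB, HeB); the edge is rising when x < ExA and
    falling otherwise (ties fall).  The drop reuses the caller's u, which
    is the uncertainty-transmission contract of cloud reasoning.
    """
    if not (0.0 < u <= 1.0):
        raise ValueError(f"certainty u must lie in (0, 1], got {u}")
    rng = as_rng(rng)
    c_b = rule.consequent
    en_b_prime = (
        0.0 if c_b.is_degenerate else float(draw_en_prime(c_b.en, c_b.he, 1, rng)[0])
    )
    offset = en_b_prime * math.sqrt(-2.0 * math.log(u))
    if x < rule.antecedent.ex:
        edge, b = "rising", c_b.ex - offset
    else:
        edge, b = "falling", c_b.ex + offset
    return InferenceResult(
        b=b, u=u, edge=edge, en_a_prime=en_a_prime, en_b_prime=en_b_prime
    )


def single_rule_infer(
    x: float, rule: InferenceRule, rng: SeedLike = None
) -> InferenceResult:
    """Activate the antecedent and emit the consequent with a shared u."""
    rng = as_rng(rng)
    u, en_a_prime = activate_antecedent(x, rule, rng)
    return emit_consequent(u, x, rule, rng, en_a_prime=en_a_prime)


def multi_rule_infer(
    x: float, rules: Sequence[InferenceRule], rng: SeedLike = None
) -> tuple[InferenceResult, int]:
    """Fire the rule whose antecedent activates x most strongly.

    Activates every rule, keeps the one with maximal certainty, and emits
    through it; returns (result, index of the winning rule).  This
    maximum-activation aggregation is an extension of the single-rule
    machinery, documented as such — not part of the core reasoning model.
    """
    if not rules:
        raise ValueError("need at least one rule")
    rng = as_rng(rng)
    activations = [activate_antecedent(x, rule, rng) for rule in rules]
    winner = int(np.argmax([u for u, _ in activations]))
    u, en_a_prime = activations[winner]
    result = emit_consequent(u, x, rules[winner], rng, en_a_prime=en_a_prime)
    return result, winner


@dataclass
class PredictionReport:
    """Aggregated predictions, one record per input index.

    ``records`` holds dicts with keys input, mean_b, sd_b, n_drops,
    converged, iterations; ``drops`` maps each input to its (b, u) drop
    DataFrame.
    """

    rule: InferenceRule
    records: list = field(default_factory=list)
    drops: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return all(r["converged"] for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_dict(self) -> dict:
        return {
            "rule": self.rule.to_dict(),
            "converged": self.converged,
            "predictions": self.records,
        }

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary(self) -> str:
        header = (
            f"{'input':>10} {'mean_b':>10} {'sd_b':>10} {'n_drops':>8} {'status':>10}"
        )
        lines = [
            "Cloud-reasoning prediction report",
            "=" * len(header),
            header,
            "-" * len(header),
        ]
        for r in self.records:
            status = "ok" if r["converged"] else "failed"
            lines.append(
                f"{r['input']:>10.4g} {r['mean_b']:>10.4f} {r['sd_b']:>10.4f} "
                f"{r['n_drops']:>8d} {status:>10}"
            )
        lines.append("=" * len(header))
        return "\n".join(lines)


def predict_mental_health(
    current_indices: Sequence[float],
    rule: Optional[InferenceRule] = None,
    history: Optional[pd.DataFrame] = None,
    trend: Optional[pd.DataFrame] = None,
    config: Optional[PredictionConfig] = None,
) -> PredictionReport:
    """Five-step prediction pipeline over current mental-health indices.

    Either supply ``rule`` directly, or supply ``history`` drops (index
    universe) and ``trend`` drops (problem-level universe): the reverse
    cloud generator then estimates the antecedent and consequent concepts.

    For each input index, ``config.n_drops`` single-rule inferences are
    drawn and summarised by their arithmetic mean and standard deviation.
    A prediction is emitted once the mean level is > 0; otherwise the batch
    is redrawn, up to ``config.max_iterations`` times, after which the
    record is marked non-converged (never an infinite loop).
    """
    if config is None:
        config = PredictionConfig()
    indices = [float(v) for v in current_indices]
    if not indices:
        raise ValueError("current_indices must be non-empty")
    if rule is None:
        if history is None or trend is None:
            raise ValueError("supply either rule, or history and trend drops")
        c_a = ReverseCloudModel.from_drops(history).fit().concept
        c_b = ReverseCloudModel.from_drops(trend).fit().concept
        rule = InferenceRule(antecedent=c_a, consequent=c_b)

    rng = as_rng(config.seed)
    report = PredictionReport(rule=rule)
    for x in indices:
        converged = False
        b = u = np.empty(0)
        iterations = 0
        for iterations in range(1, config.max_iterations + 1):
            results = [single_rule_infer(x, rule, rng) for _ in range(config.n_drops)]
            b = np.array([r.b for r in results])
            u = np.array([r.u for r in results])
            if b.mean() > 0:
                converged = True
                break
        sd = float(b.std(ddof=1)) if len(b) > 1 else 0.0
        report.records.append(
            {
                "input": x,
                "mean_b": float(b.mean()),
                "sd_b": sd,
                "n_drops": int(len(b)),
                "converged": converged,
                "iterations": iterations,
            }
        )
        report.drops[x] = pd.DataFrame({"b": b, "u": u})
    return report
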