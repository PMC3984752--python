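"""Confidence-weighted fuzzy classification of risk level.

A mined rule base stratifies a patient case by scoring each risk class as

    v_class = sum over that class's rules of Confidence(r) * beta(r, sigma)

where the firing strength beta(r, sigma) is the SUM over the rule's
antecedent features of the maximal selected-term membership (a sum, not an
average, so beta may exceed 1).  The predicted level is the arg-max score;
ties break toward the higher risk level (the clinically conservative
choice).  When no rule fires at all, the prediction falls back to a
configured default class and is flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .data import Dataset, PatientCase, RiskLabel, RISK_LEVELS
from .partition import FuzzyPartition
from .rules import FeatureMatrices, FuzzyRule, RuleSpace, rule_to_text


def firing_strength(
    rule: FuzzyRule, sigma: PatientCase, space: RuleSpace
) -> float:
    """Sum over antecedent features of the max selected-term membership.

    Bounded by the number of antecedent features; a categorical match
    contributes 1, a mismatch or missing value 0.
    """
    return sum(
        space.selection_membership(sel, sigma.get(sel.feature))
        for sel in rule.antecedent
    )


@dataclass(frozen=True)
class ScoreVector:
    """Per-class accumulated rule votes (non-negative)."""

    v_low: float
    v_medium: float
    v_high: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.v_low, self.v_medium, self.v_high)

    def argmax(self) -> RiskLabel:
        """Highest-scoring class; ties go to the higher risk level."""
        scores = self.as_tuple()
        best = max(scores)
        for cls in reversed(RISK_LEVELS):
            if scores[cls.rank] == best:
                return cls
        raise AssertionError("unreachable")


@dataclass
class Prediction:
    """The scored risk assessment of one case."""

    case_id: str
    scores: ScoreVector
    label: RiskLabel
    no_rule_fired: bool = False
    fired_rules: list[tuple[FuzzyRule, float]] = field(default_factory=list)


class RuleBase:
    """The mined per-class rule collection plus its fuzzy partitions."""

    def __init__(
        self,
        rules: Sequence[FuzzyRule],
        partitions: Mapping[str, FuzzyPartition],
        provenance: dict | None = None,
        fallback: RiskLabel = RiskLabel.MEDIUM,
    ) -> None:
        self.rules = list(rules)
        self.partitions = dict(partitions)
        self.provenance = provenance or {}
        self.fallback = fallback
        for r in self.rules:
            if r.stats.get("confidence") is None:
                raise ValueError("rule base contains a rule with undefined confidence")

    def by_class(self, cls: RiskLabel) -> list[FuzzyRule]:
        return [r for r in self.rules if r.consequent is cls]

    def __len__(self) -> int:
        return len(self.rules)

    def space(self, schema) -> RuleSpace:
        return RuleSpace(schema, self.partitions)

    # -- persistence -------------------------------------------------------

    def to_json(self, space: RuleSpace) -> list[dict]:
        doc = []
        for r in self.rules:
            chrom = space.encode(r)
            doc.append(
                {
                    "class": r.consequent.level,
                    "bits": "".join(str(b) for b in chrom.bits),
                    "readable": rule_to_text(r, space),
                    "support": r.stats.get("support"),
                    "confidence": r.stats.get("confidence"),
                    "fitness": r.stats.get("fitness"),
                }
            )
        return doc

    def save(self, path, space: RuleSpace) -> None:
        doc = {
            "provenance": self.provenance,
            "fallback": self.fallback.level,
            "partitions": [p.to_dict() for p in self.partitions.values()],
            "rules": self.to_json(space),
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path, schema) -> "RuleBase":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        partitions = {
            p["feature"]: FuzzyPartition.from_dict(p) for p in doc["partitions"]
        }
        space = RuleSpace(schema, partitions)
        rules = []
        for entry in doc["rules"]:
            from .rules import Chromosome

            bits = tuple(int(b) for b in entry["bits"])
            rule = space.decode(Chromosome(bits, RiskLabel.parse(entry["class"])))
            rule.stats = {
                "support": entry.get("support"),
                "confidence": entry.get("confidence"),
                "fitness": entry.get("fitness"),
            }
            rules.append(rule)
        return cls(
            rules,
            partitions,
            provenance=doc.get("provenance", {}),
            fallback=RiskLabel.parse(doc.get("fallback", "medium-risk")),
        )

    def pretty(self, space: RuleSpace) -> str:
        """Plain-text rule listing with support/confidence/fitness columns."""
        lines = []
        for cls in RISK_LEVELS:
            section = self.by_class(cls)
            if not section:
                continue
            lines.append(f"== {cls.level} ({len(section)} rules) ==")
            for i, r in enumerate(section, 1):
                st = r.stats
                lines.append(
                    f"{i}. {rule_to_text(r, space)}  "
                    f"[support={st.get('support', float('nan')):.3f} "
                    f"confidence={st.get('confidence', float('nan')):.3f} "
                    f"fitness={st.get('fitness', float('nan')):.3f}]"
                )
        return "\n".join(lines)


def score(rb: RuleBase, sigma: PatientCase, space: RuleSpace) -> ScoreVector:
    """Per-class sum of confidence-weighted firing strengths."""
    totals = [0.0, 0.0, 0.0]
    for rule in rb.rules:
        beta = firing_strength(rule, sigma, space)
        totals[rule.consequent.rank] += rule.stats["confidence"] * beta
    return ScoreVector(*totals)


def predict(rb: RuleBase, sigma: PatientCase, space: RuleSpace) -> Prediction:
    """Classify one case; falls back (flagged) when no rule fires."""
    fired: list[tuple[FuzzyRule, float]] = []
    totals = [0.0, 0.0, 0.0]
    for rule in rb.rules:
        beta = firing_strength(rule, sigma, space)
        if beta > 0.0:
            fired.append((rule, beta))
            totals[rule.consequent.rank] += rule.stats["confidence"] * beta
    scores = ScoreVector(*totals)
    if not fired:
        return Prediction(sigma.id, scores, rb.fallback, no_rule_fired=True)
    return Prediction(sigma.id, scores, scores.argmax(), fired_rules=fired)


def predict_batch(
    rb: RuleBase, d: Dataset, space: RuleSpace | None = None
) -> list[Prediction]:
    """Order-preserving batch classification (vectorised over cases)."""
    if space is None:
        space = RuleSpace(d.schema, rb.partitions)
    if len(d) == 0:
        return []
    matrices = FeatureMatrices(space, d)
    n = len(d)
    totals = np.zeros((n, 3))
    any_fired = np.zeros(n, dtype=bool)
    for rule in rb.rules:
        beta = matrices.rule_firing(rule)
        totals[:, rule.consequent.rank] += rule.stats["confidence"] * beta
        any_fired |= beta > 0.0
    out = []
    for i, case in enumerate(d):
        scores = ScoreVector(*totals[i])
        if not any_fired[i]:
            out.append(Prediction(case.id, scores, rb.fallback, no_rule_fired=True))
        else:
            out.append(Prediction(case.id, scores, scores.argmax()))
    return out
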