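"""Synthetic patient cohorts with planted fuzzy ground truth.

The study's 54-case hospital cohort is not public, so this module generates
cohorts with the same feature structure (9 numerical + 17 categorical
clinical features) whose risk labels are produced by a *known* planted fuzzy
rule set, scored with the package's own confidence-weighted classifier.
That gives every pipeline stage a ground-truth oracle: a miner that works
should re-discover rules whose predictions agree with the planted labels on
held-out data.

Feature values are drawn independently: numerical features from truncated
normal distributions over clinically plausible spans (conventions, declared
below, not literature claims), categorical features from weighted token
draws.  Class mix is enforced exactly by stratified rejection (default mix
16:33:5 low:medium:high out of 54, the imbalance typical of unstable-angina
cohorts), then each label is flipped to a uniformly different class with a
small probability to emulate physician disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import truncnorm

from .classify import RuleBase, predict_batch
from .data import (
    Dataset,
    FeatureSchema,
    PatientCase,
    RiskLabel,
    RISK_LEVELS,
    load_dataset,
    load_schema,
)
from .partition import FuzzyPartition
from .rules import FuzzyRule, LabelSelection, RuleSpace


class GenerationError(RuntimeError):
    """The requested class mix could not be met within the draw budget."""


#: (mean, sd, low, high) for each numerical feature; spans are conventional
#: clinical ranges (age in years, pressures mmHg, creatinine umol/L, enzymes
#: U/L, troponin ng/mL).
DEFAULT_NUMERICAL: dict[str, tuple[float, float, float, float]] = {
    "age": (62, 12, 30, 90),
    "sbp": (132, 20, 80, 200),
    "dbp": (78, 12, 40, 120),
    "creatinine": (90, 35, 40, 250),
    "ast": (40, 40, 5, 300),
    "ldh": (220, 90, 80, 600),
    "ck": (160, 150, 20, 1000),
    "ck_mb": (18, 14, 0, 100),
    "cnt": (0.8, 1.5, 0.0, 10.0),
}

#: token -> probability for each categorical feature.
DEFAULT_CATEGORICAL: dict[str, dict[str, float]] = {
    "sex": {"male": 0.55, "female": 0.45},
    "smoke": {"yes": 0.40, "no": 0.60},
    "atrial_premature_beat": {"yes": 0.15, "no": 0.85},
    "st_change": {"yes": 0.12, "no": 0.88},
    "heart_events_recently": {"yes": 0.45, "no": 0.55},
    "coronary_heart_disease": {"yes": 0.50, "no": 0.50},
    "renal_insufficiency": {"yes": 0.10, "no": 0.90},
    "bleeding": {"yes": 0.05, "no": 0.95},
    "diabetes": {"none": 0.60, "type 1": 0.05, "type 2": 0.35},
    "hyperlipaemia": {"yes": 0.35, "no": 0.65},
    "hypertension": {"none": 0.30, "level I": 0.25, "level II": 0.25,
                     "level III": 0.20},
    "aspirin_recent_7d": {"yes": 0.50, "no": 0.50},
    "pci": {"yes": 0.30, "no": 0.70},
    "lung_blood_expectoration": {"yes": 0.05, "no": 0.95},
    "t_change": {"yes": 0.35, "no": 0.65},
    "heart_event_by_drinking": {"yes": 0.10, "no": 0.90},
    "irregular_pulse": {"yes": 0.20, "no": 0.80},
}

#: Class-mix fractions matching the 16/33/5 low/medium/high imbalance.
DEFAULT_CLASS_MIX: dict[RiskLabel, float] = {
    RiskLabel.LOW: 16 / 54,
    RiskLabel.MEDIUM: 33 / 54,
    RiskLabel.HIGH: 5 / 54,
}


def default_schema() -> list[FeatureSchema]:
    """The 26-feature clinical schema: 9 numerical + 17 categorical."""
    schema = [
        FeatureSchema(name, "numerical") for name in DEFAULT_NUMERICAL
    ]
    schema += [
        FeatureSchema(name, "categorical", list(tokens))
        for name, tokens in DEFAULT_CATEGORICAL.items()
    ]
    return schema


#: Fixed, known partitions the planted rules are written against
#: (feature -> (midpoints, labels)); bounds come from DEFAULT_NUMERICAL.
#: Midpoints sit where clustering of the marginal distributions places
#: them, so the terms the planted rules speak match the linguistic terms a
#: fitted partition will offer the miner.
_PLANTED_PARTITIONS: dict[str, tuple[list[float], list[str]]] = {
    "age": ([48, 63], ["young", "middle-aged", "old", "very old"]),
    "sbp": ([125], ["low", "medium", "high"]),
    "dbp": ([76], ["low", "medium", "high"]),
    "creatinine": ([120], ["low", "medium", "high"]),
    "ast": ([72], ["low", "medium", "high"]),
    "ldh": ([219, 393], ["low", "medium", "high", "very high"]),
    "ck": ([280], ["low", "medium", "high"]),
    "ck_mb": ([15, 35], ["very low", "low", "medium", "high"]),
    "cnt": ([1.0, 2.9], ["low", "mild", "raised", "high"]),
}


@dataclass
class GeneratorConfig:
    """Settings of the synthetic cohort generator."""

    n_cases: int
    schema: list[FeatureSchema] = field(default_factory=default_schema)
    numerical: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NUMERICAL)
    )
    categorical: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CATEGORICAL.items()}
    )
    label_noise: float = 0.05
    class_mix: dict[RiskLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        for name, weights in self.categorical.items():
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"categorical weights for {name!r} sum to {total}, not 1"
                )
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-6:
            raise ValueError("class-mix fractions must sum to 1")


@dataclass
class PlantedRuleSet:
    """Known ground-truth rules over fixed partitions.

    Labelling uses the classifier's own scoring, so ties follow its
    conservative toward-higher-risk policy; a case firing no planted rule
    falls back to medium-risk.
    """

    rules: list[FuzzyRule]
    partitions: dict[str, FuzzyPartition]
    fallback: RiskLabel = RiskLabel.MEDIUM

    def rule_base(self) -> RuleBase:
        return RuleBase(
            self.rules, self.partitions,
            provenance={"planted": True}, fallback=self.fallback,
        )


def _planted_partitions() -> dict[str, FuzzyPartition]:
    parts = {}
    for name, (mids, labels) in _PLANTED_PARTITIONS.items():
        _, _, lo, hi = DEFAULT_NUMERICAL[name]
        parts[name] = FuzzyPartition(name, lo, mids, hi, labels)
    return parts


def _mask(terms: Sequence[str], selected: Sequence[str]) -> tuple[int, ...]:
    sel = set(selected)
    return tuple(1 if t in sel else 0 for t in terms)


def default_planted() -> PlantedRuleSet:
    """The shipped ground-truth rule set.

    The three strata mirror how risk presents clinically: high risk is the
    ischaemic-ECG stratum (significant ST change, reinforced by strongly
    elevated CK-MB/LDH); low risk is younger patients with a quiet history
    (no recent events, no coronary history, quiet ECG); medium risk is the
    broad remainder, expressed through weak base-rate, recent heart-event,
    and advanced-age rules.  Confidence weights are set so the planted
    scoring assigns every case exactly one stratum: an ST change always
    wins, youth and a quiet history beat the medium base rules, and partial
    marker firings cannot claim high risk on a quiet ECG.
    """
    parts = _planted_partitions()
    space = RuleSpace(default_schema(), parts)

    def rule(cls: RiskLabel, confidence: float, **selections) -> FuzzyRule:
        ants = [
            LabelSelection(feat, _mask(space.terms[feat], sel))
            for feat, sel in selections.items()
        ]
        r = FuzzyRule(ants, cls)
        r.stats = {"support": None, "confidence": confidence,
                   "fitness": None}
        return r

    rules = [
        rule(RiskLabel.LOW, 0.40,
             heart_events_recently=["no"], coronary_heart_disease=["no"],
             st_change=["no"]),
        rule(RiskLabel.LOW, 0.35,
             age=["young", "middle-aged"]),
        rule(RiskLabel.MEDIUM, 0.45,
             bleeding=["no"]),
        rule(RiskLabel.MEDIUM, 0.45,
             heart_events_recently=["yes"]),
        rule(RiskLabel.MEDIUM, 0.40,
             age=["old", "very old"]),
        rule(RiskLabel.HIGH, 1.00,
             st_change=["yes"]),
        rule(RiskLabel.HIGH, 0.80,
             st_change=["yes"], ck_mb=["high"], ldh=["very high"]),
    ]
    return PlantedRuleSet(rules, parts)


def _quotas(mix: Mapping[RiskLabel, float], n: int) -> dict[RiskLabel, int]:
    """Largest-remainder apportionment of n cases to the mix fractions."""
    raw = {cls: mix.get(cls, 0.0) * n for cls in RISK_LEVELS}
    base = {cls: int(np.floor(v)) for cls, v in raw.items()}
    short = n - sum(base.values())
    order = sorted(RISK_LEVELS, key=lambda c: raw[c] - base[c], reverse=True)
    for cls in order[:short]:
        base[cls] += 1
    return base


def _draw_batch(
    cfg: GeneratorConfig, size: int, rng: np.random.Generator, start_id: int
) -> list[PatientCase]:
    columns: dict[str, np.ndarray] = {}
    for feat in cfg.schema:
        if feat.is_numerical:
            mean, sd, lo, hi = cfg.numerical[feat.name]
            a, b = (lo - mean) / sd, (hi - mean) / sd
            vals = truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                                 random_state=rng)
            columns[feat.name] = np.round(vals, 2)
        else:
            tokens = list(cfg.categorical[feat.name])
            probs = [cfg.categorical[feat.name][t] for t in tokens]
            columns[feat.name] = rng.choice(tokens, p=probs, size=size)
    return [
        PatientCase(
            f"case_{start_id + i:05d}",
            {f.name: (float(columns[f.name][i]) if f.is_numerical
                      else str(columns[f.name][i]))
             for f in cfg.schema},
        )
        for i in range(size)
    ]


def generate(
    cfg: GeneratorConfig, planted: PlantedRuleSet | None = None
) -> Dataset:
    """Draw a cohort, label it with the planted rules, enforce the mix.

    Cases are drawn in batches, scored against the planted rule base with
    the classifier itself, and accepted into per-class quotas (stratified
    rejection).  After the quotas fill, case order is shuffled and each
    label flips to a uniformly different class with probability
    ``cfg.label_noise``.  Fully determined by ``cfg.seed``; raises
    :class:`GenerationError` if the quotas cannot be met within ``10 *
    n_cases`` draws.
    """
    planted = planted or default_planted()
    schema_names = {f.name for f in cfg.schema}
    for r in planted.rules:
        for sel in r.antecedent:
            if sel.feature not in schema_names:
                raise ValueError(
                    f"planted rule references unknown feature {sel.feature!r}"
                )
    rng = np.random.default_rng(cfg.seed)
    rb = planted.rule_base()
    quotas = _quotas(cfg.class_mix, cfg.n_cases)
    accepted: list[PatientCase] = []
    filled = {cls: 0 for cls in RISK_LEVELS}
    drawn = 0
    budget = 10 * cfg.n_cases
    while drawn < budget and any(filled[c] < quotas[c] for c in RISK_LEVELS):
        size = min(max(cfg.n_cases, 128), budget - drawn)
        batch = _draw_batch(cfg, size, rng, start_id=drawn)
        drawn += size
        batch_ds = Dataset([FeatureSchema(f.name, f.kind,
                                          None if f.is_numerical else list(f.domain))
                            for f in cfg.schema], batch)
        preds = predict_batch(rb, batch_ds)
        for case, pred in zip(batch, preds):
            if filled[pred.label] < quotas[pred.label]:
                case.label = pred.label
                accepted.append(case)
                filled[pred.label] += 1
    if any(filled[c] < quotas[c] for c in RISK_LEVELS):
        missing = {c.level: quotas[c] - filled[c] for c in RISK_LEVELS
                   if filled[c] < quotas[c]}
        raise GenerationError(
            f"class mix unsatisfiable within {budget} draws; missing {missing}"
        )
    order = rng.permutation(len(accepted))
    cases = []
    for i, j in enumerate(order):
        case = accepted[j]
        label = case.label
        if cfg.label_noise > 0 and rng.random() < cfg.label_noise:
            others = [c for c in RISK_LEVELS if c is not label]
            label = others[int(rng.integers(2))]
        cases.append(PatientCase(f"case_{i + 1:05d}", dict(case.values), label))
    schema = [FeatureSchema(f.name, f.kind,
                            None if f.is_numerical else list(f.domain))
              for f in cfg.schema]
    return Dataset(schema, cases)


def table1_fixture() -> Dataset:
    """The six-case teaching cohort shipped with the package.

    One numerical feature (age) and three categorical features (sex,
    smoking, recent heart events) with physician labels; ages are
    {74, 81, 74, 71, 76, 67}.
    """
    pkg = resources.files("gfsrisk.fixtures")
    with resources.as_file(pkg / "table1_schema.json") as p:
        schema = load_schema(p)
    with resources.as_file(pkg / "table1.csv") as p:
        return load_dataset(p, schema)


#: Age partition used throughout the teaching example: ages 30-87 split at
#: midpoints 56 and 74 into young / middle-aged / old / very old.
def toy_age_partition() -> FuzzyPartition:
    return FuzzyPartition(
        "age", 30, [56, 74], 87, ["young", "middle-aged", "old", "very old"]
    )


def toy_rule_base() -> RuleBase:
    """The six-rule teaching rule base for the six-case fixture.

    Two rules per risk class over the :func:`toy_age_partition`, with their
    support/confidence quality measures as computed on the fixture; the
    classifier weighs votes by these confidences.
    """
    parts = {"age": toy_age_partition()}
    space = RuleSpace(table1_fixture().schema, parts)

    def rule(cls: RiskLabel, sup: float, conf: float, **sels) -> FuzzyRule:
        ants = [
            LabelSelection(f, _mask(space.terms[f], sel))
            for f, sel in sels.items()
        ]
        r = FuzzyRule(ants, cls)
        r.stats = {"support": sup, "confidence": conf,
                   "fitness": (sup + conf) / 2}
        return r

    rules = [
        rule(RiskLabel.LOW, 0.083, 0.5,
             age=["young"], heart_events_recently=["no"]),
        rule(RiskLabel.LOW, 0.11, 0.33,
             age=["young"], sex=["female"], smoking=["no"]),
        rule(RiskLabel.MEDIUM, 0.244, 0.514,
             age=["young", "middle-aged"], smoking=["no"],
             heart_events_recently=["yes"]),
        rule(RiskLabel.MEDIUM, 0.339, 0.465,
             age=["old"], smoking=["no"]),
        rule(RiskLabel.HIGH, 0.269, 0.377,
             age=["old", "very old"], smoking=["yes"]),
        rule(RiskLabel.HIGH, 0.324, 0.455,
             age=["middle-aged", "old", "very old"], sex=["male"],
             heart_events_recently=["yes"]),
    ]
    return RuleBase(rules, parts, provenance={"teaching_example": True})


def recovery_score(
    mined: RuleBase, planted: PlantedRuleSet, test: Dataset
) -> float:
    """Agreement of the mined base with noise-free planted labels.

    Both rule bases classify the held-out cohort; the score is the fraction
    of cases on which they agree.  In [0, 1]; 1 when the mined base
    reproduces the planted labelling exactly.
    """
    mined_feats = set()
    for r in mined.rules:
        mined_feats.update(sel.feature for sel in r.antecedent)
    test_feats = set(test.feature_names)
    if not mined_feats <= test_feats:
        raise ValueError("mined rule base does not match the test schema")
    truth = [p.label for p in predict_batch(planted.rule_base(), test)]
    preds = [p.label for p in predict_batch(mined, test)]
    return sum(a is b for a, b in zip(preds, truth)) / len(test)
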