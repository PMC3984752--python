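"""Fuzzy association rules: representation, encoding, and quality measures.

A rule has the form ``IF a1 is (l1 or l3) and a5 is l4 THEN <risk level>``:
the antecedent selects, per feature, a disjunction of linguistic terms
(numerical features) or domain tokens (categorical features); the consequent
is exactly one risk level.

The genetic encoding is a concatenation of per-feature bitmasks in schema
order, one bit per term/token.  A segment that is all zeros or all ones
carries no information and marks its feature irrelevant (excluded from the
antecedent).

Rule quality on a labelled cohort D:

* antecedent part compatibility  APC(sigma, r) — the mean, over the rule's
  relevant features, of the maximal membership of sigma's value among the
  selected terms (categorical memberships are 0/1; missing values are 0);
* Supp(sigma, r) = APC(sigma, r) when sigma's label equals the rule's class,
  else 0;
* Support(r)    = sum_sigma Supp / |D|;
* Confidence(r) = sum_sigma Supp / sum_sigma APC.

``rule_fitness`` combines them as (Support + Confidence) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import Dataset, FeatureSchema, PatientCase, RiskLabel, _norm_token
from .partition import FuzzyPartition


class EncodingError(ValueError):
    """Rule/chromosome does not fit the schema layout."""


class InvalidRuleError(ValueError):
    """Every feature irrelevant: the chromosome encodes no rule."""


class UndefinedConfidenceError(ZeroDivisionError):
    """The rule fires on no case, so confidence has no value."""


@dataclass(frozen=True)
class LabelSelection:
    """A per-feature disjunction of selected terms, as a bitmask."""

    feature: str
    mask: tuple[int, ...]

    @property
    def is_relevant(self) -> bool:
        return 0 < sum(self.mask) < len(self.mask)


@dataclass
class FuzzyRule:
    """An IF-THEN rule with a per-feature-disjunction antecedent."""

    antecedent: list[LabelSelection]
    consequent: RiskLabel
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        kept = [s for s in self.antecedent if s.is_relevant]
        if not kept:
            raise InvalidRuleError("rule has no relevant antecedent feature")
        self.antecedent = kept

    @property
    def n_features(self) -> int:
        return len(self.antecedent)

    def selection(self, feature: str) -> LabelSelection | None:
        for s in self.antecedent:
            if s.feature == feature:
                return s
        return None

    def key(self) -> tuple:
        """Canonical identity: consequent + sorted relevant selections."""
        return (
            self.consequent.value,
            tuple(sorted((s.feature, s.mask) for s in self.antecedent)),
        )


@dataclass(frozen=True)
class Chromosome:
    """Flat bit string over the full schema layout, plus a fixed class.

    The class is fixed per mining run and is not evolved.
    """

    bits: tuple[int, ...]
    cls: RiskLabel

    def __len__(self) -> int:
        return len(self.bits)


class RuleSpace:
    """Schema-with-partitions: the layout rules and chromosomes live in.

    Binds the feature schema to the fuzzy partitions of its numerical
    features and owns the segment layout of the genetic encoding, the
    encode/decode maps, and the per-feature term membership computations.
    """

    def __init__(
        self,
        schema: Sequence[FeatureSchema],
        partitions: Mapping[str, FuzzyPartition],
    ) -> None:
        self.schema = list(schema)
        self.partitions = dict(partitions)
        self.features: list[str] = []
        self.terms: dict[str, list[str]] = {}
        self._offsets: dict[str, int] = {}
        offset = 0
        for feat in self.schema:
            if feat.is_numerical:
                if feat.name not in self.partitions:
                    raise EncodingError(
                        f"no fuzzy partition for numerical feature {feat.name!r}"
                    )
                terms = list(self.partitions[feat.name].labels)
            else:
                terms = [str(t) for t in feat.domain]
            self.features.append(feat.name)
            self.terms[feat.name] = terms
            self._offsets[feat.name] = offset
            offset += len(terms)
        self.n_bits = offset
        self._by_name = {f.name: f for f in self.schema}

    def segment_length(self, feature: str) -> int:
        return len(self.terms[feature])

    def segment(self, chrom: Chromosome, feature: str) -> tuple[int, ...]:
        o = self._offsets[feature]
        return chrom.bits[o: o + self.segment_length(feature)]

    # -- encode / decode ---------------------------------------------------

    def encode(self, rule: FuzzyRule) -> Chromosome:
        """Lay the rule out as a flat bit string (irrelevant = all zeros)."""
        bits: list[int] = []
        for name in self.features:
            sel = rule.selection(name)
            k = self.segment_length(name)
            if sel is None:
                bits.extend([0] * k)
            elif len(sel.mask) != k:
                raise EncodingError(
                    f"mask length {len(sel.mask)} != {k} terms "
                    f"for feature {name!r}"
                )
            else:
                bits.extend(int(b) for b in sel.mask)
        for sel in rule.antecedent:
            if sel.feature not in self._offsets:
                raise EncodingError(f"unknown feature {sel.feature!r} in rule")
        return Chromosome(tuple(bits), rule.consequent)

    def decode(self, chrom: Chromosome) -> FuzzyRule:
        """Drop all-zero/all-one segments; raise if nothing remains."""
        if len(chrom.bits) != self.n_bits:
            raise EncodingError(
                f"chromosome length {len(chrom.bits)} != layout {self.n_bits}"
            )
        selections = []
        for name in self.features:
            mask = self.segment(chrom, name)
            sel = LabelSelection(name, tuple(int(b) for b in mask))
            if sel.is_relevant:
                selections.append(sel)
        if not selections:
            raise InvalidRuleError("all segments irrelevant")
        return FuzzyRule(selections, chrom.cls)

    # -- memberships -------------------------------------------------------

    def term_membership(self, feature: str, value) -> np.ndarray:
        """Memberships of one case value in every term of one feature."""
        k = self.segment_length(feature)
        if value is None:
            return np.zeros(k)
        feat = self._by_name[feature]
        if feat.is_numerical:
            part = self.partitions[feature]
            return np.array(
                [part.membership(j, float(value)) for j in range(k)]
            )
        out = np.zeros(k)
        out[feat.domain_index(value)] = 1.0
        return out

    def selection_membership(self, sel: LabelSelection, value) -> float:
        """Max membership of a value among the terms the mask selects."""
        mu = self.term_membership(sel.feature, value)
        mask = np.asarray(sel.mask, dtype=bool)
        return float(mu[mask].max()) if mask.any() else 0.0


# ---------------------------------------------------------------------------
# Scalar quality measures (the readable reference path; the GA uses the
# vectorised FeatureMatrices below and tests assert the two agree).

def apc(
    sigma: PatientCase,
    rule: FuzzyRule,
    space: RuleSpace,
    denominator: str = "antecedent",
) -> float:
    """Antecedent part compatibility of a case with a rule, in [0, 1].

    The mean over the rule's relevant features of the maximal selected-term
    membership.  With ``denominator="all"`` the mean is taken over every
    schema feature instead (a sensitivity-analysis variant in which
    irrelevant features dilute the compatibility).
    """
    total = sum(
        space.selection_membership(sel, sigma.get(sel.feature))
        for sel in rule.antecedent
    )
    n = len(space.features) if denominator == "all" else rule.n_features
    return total / n


def supp(
    sigma: PatientCase, rule: FuzzyRule, space: RuleSpace, **kw
) -> float:
    """Support degree of one case: APC if the labels agree, else 0."""
    if sigma.label is None:
        raise ValueError(f"case {sigma.id} is unlabelled")
    if sigma.label is not rule.consequent:
        return 0.0
    return apc(sigma, rule, space, **kw)


def support(rule: FuzzyRule, d: Dataset, space: RuleSpace, **kw) -> float:
    """Mean support degree over the cohort."""
    if len(d) == 0:
        raise ValueError("empty dataset")
    return sum(supp(s, rule, space, **kw) for s in d) / len(d)


def confidence(rule: FuzzyRule, d: Dataset, space: RuleSpace, **kw) -> float:
    """Class-matching coverage over total coverage."""
    if len(d) == 0:
        raise ValueError("empty dataset")
    apc_sum = sum(apc(s, rule, space, **kw) for s in d)
    if apc_sum <= 0.0:
        raise UndefinedConfidenceError("rule fires on no case")
    return sum(supp(s, rule, space, **kw) for s in d) / apc_sum


def rule_fitness(rule: FuzzyRule, d: Dataset, space: RuleSpace, **kw) -> float:
    """Composite quality: mean of support and confidence; 0 when undefined."""
    try:
        return (support(rule, d, space, **kw) + confidence(rule, d, space, **kw)) / 2
    except (UndefinedConfidenceError, InvalidRuleError):
        return 0.0


def combine_fitness(support_value: float, confidence_value: float) -> float:
    """The fitness combination applied to already-computed rule measures."""
    return (support_value + confidence_value) / 2.0


def evaluate_rule(
    rule: FuzzyRule, d: Dataset, space: RuleSpace, **kw
) -> dict:
    """Compute and cache support/confidence/fitness on the rule."""
    s = support(rule, d, space, **kw)
    try:
        c = confidence(rule, d, space, **kw)
        stats = {"support": s, "confidence": c, "fitness": combine_fitness(s, c)}
    except UndefinedConfidenceError:
        stats = {"support": s, "confidence": None, "fitness": 0.0}
    stats["dataset_key"] = id(d)
    rule.stats = stats
    return stats


#: Default support-equality tolerance for the redundancy test.  Exact
#: equality only occurs on small discrete cohorts; on continuous data a
#: specialised copy of a rule (an extra near-universal token appended)
#: shifts support by a fraction of a percent while adding nothing, so
#: "same support" is read as agreement within one support point.
REDUNDANCY_TOL = 0.01


def is_redundant(
    r1: FuzzyRule, r2: FuzzyRule, d: Dataset, space: RuleSpace,
    tol: float = REDUNDANCY_TOL, **kw,
) -> bool:
    """True when r1 adds nothing over the more general rule r2.

    Requires the same consequent, every effective mask of r1 a bitwise subset
    of r2's (features irrelevant in a rule count as unconstrained, i.e.
    all-ones), and equal support within ``tol``.
    """
    if r1.consequent is not r2.consequent:
        return False
    for name in space.features:
        k = space.segment_length(name)
        s1, s2 = r1.selection(name), r2.selection(name)
        m1 = s1.mask if s1 else (1,) * k
        m2 = s2.mask if s2 else (1,) * k
        if any(a and not b for a, b in zip(m1, m2)):
            return False
    return abs(support(r1, d, space, **kw) - support(r2, d, space, **kw)) <= tol


def rule_to_text(rule: FuzzyRule, space: RuleSpace) -> str:
    """Render a rule as an IF ... THEN ... statement."""
    parts = []
    for name in space.features:
        sel = rule.selection(name)
        if sel is None:
            continue
        terms = [t for t, b in zip(space.terms[name], sel.mask) if b]
        parts.append(f"{name} is ({' OR '.join(terms)})")
    return f"IF {' AND '.join(parts)} THEN Risk is {rule.consequent.level}"


# ---------------------------------------------------------------------------
# Vectorised evaluation over a fixed cohort.

class FeatureMatrices:
    """Per-feature term-membership matrices for one cohort.

    ``M[feature]`` has shape (n_cases, n_terms); numerical entries are fuzzy
    memberships, categorical entries one-hot token indicators, missing rows
    all zero.  On top of these, per-feature lookup tables map every possible
    segment bitmask to its max-over-selected-terms vector, which makes
    population-scale rule evaluation a handful of fancy-indexed sums.
    """

    def __init__(self, space: RuleSpace, d: Dataset,
                 denominator: str = "antecedent") -> None:
        self.space = space
        self.n = len(d)
        self.denominator = denominator
        self.labels = np.array(
            [(-1 if c.label is None else c.label.value) for c in d]
        )
        self.M: dict[str, np.ndarray] = {}
        for name in space.features:
            feat = space._by_name[name]
            if feat.is_numerical:
                xs = np.array(
                    [np.nan if c.values.get(name) is None else float(c.values[name])
                     for c in d]
                )
                self.M[name] = space.partitions[name].membership_matrix(xs)
            else:
                k = space.segment_length(name)
                mat = np.zeros((self.n, k))
                normed = [_norm_token(t) for t in feat.domain]
                for i, c in enumerate(d):
                    v = c.values.get(name)
                    if v is not None:
                        mat[i, normed.index(_norm_token(v))] = 1.0
                self.M[name] = mat
        # mask-id lookup tables: TAB[f][mask_id] = per-case max over the
        # selected terms (zeros for the two irrelevant masks), REL[f][mask_id]
        # = whether that mask makes the feature relevant.
        self.TAB: list[np.ndarray] = []
        self.REL: list[np.ndarray] = []
        for name in space.features:
            k = space.segment_length(name)
            tab = np.zeros((1 << k, self.n))
            rel = np.zeros(1 << k, dtype=bool)
            full = (1 << k) - 1
            for mid in range(1, full):
                sel = [j for j in range(k) if mid >> j & 1]
                tab[mid] = self.M[name][:, sel].max(axis=1)
                rel[mid] = True
            self.TAB.append(tab)
            self.REL.append(rel)

    def mask_ids(self, chrom: Chromosome) -> np.ndarray:
        """Per-feature integer mask ids (bit j of id = term j selected)."""
        ids = np.empty(len(self.space.features), dtype=np.int64)
        for f, name in enumerate(self.space.features):
            seg = self.space.segment(chrom, name)
            ids[f] = sum(b << j for j, b in enumerate(seg))
        return ids

    def population_stats(
        self, ids: np.ndarray, cls: RiskLabel
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Support, confidence, fitness for a population of chromosomes.

        ``ids`` has shape (pop, n_features); rows with no relevant feature or
        zero total compatibility score fitness 0 (confidence reported 0).
        """
        pop = ids.shape[0]
        acc = np.zeros((pop, self.n))
        nrel = np.zeros(pop)
        for f in range(len(self.space.features)):
            acc += self.TAB[f][ids[:, f]]
            nrel += self.REL[f][ids[:, f]]
        if self.denominator == "all":
            denom = np.full(pop, float(len(self.space.features)))
        else:
            denom = nrel
        valid = nrel > 0
        apc_mat = np.zeros_like(acc)
        apc_mat[valid] = acc[valid] / denom[valid, None]
        match = (self.labels == cls.value).astype(float)
        supp_mat = apc_mat * match[None, :]
        sup = supp_mat.mean(axis=1)
        apc_tot = apc_mat.sum(axis=1)
        fires = apc_tot > 0
        conf = np.zeros(pop)
        conf[fires] = supp_mat.sum(axis=1)[fires] / apc_tot[fires]
        fit = np.where(valid & fires, (sup + conf) / 2.0, 0.0)
        return sup, conf, fit

    def rule_firing(self, rule: FuzzyRule) -> np.ndarray:
        """Firing strength (sum of per-feature maxima) for every case."""
        beta = np.zeros(self.n)
        for sel in rule.antecedent:
            f = self.space.features.index(sel.feature)
            mid = sum(b << j for j, b in enumerate(sel.mask))
            beta += self.TAB[f][mid]
        return beta
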