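import numpy as np
import pytest

from gfsrisk import RISK_LEVELS, RiskLabel
from gfsrisk.data import PatientCase
from gfsrisk.rules import (
    Chromosome,
    EncodingError,
    FeatureMatrices,
    FuzzyRule,
    InvalidRuleError,
    LabelSelection,
    RuleSpace,
    UndefinedConfidenceError,
    apc,
    combine_fitness,
    confidence,
    evaluate_rule,
    is_redundant,
    rule_to_text,
    supp,
    support,
)


def make_rule(space, cls, **selections):
    ants = [
        LabelSelection(
            f, tuple(1 if t in set(sel) else 0 for t in space.terms[f])
        )
        for f, sel in selections.items()
    ]
    return FuzzyRule(ants, cls)


class TestEncoding:
    def test_layout_follows_schema_order(self, toy_space):
        # age(4) + sex(2) + smoking(2) + events(2) = 10 bits
        assert toy_space.n_bits == 10

    def test_reference_rule_encodes_to_printed_bit_string(self, toy_space):
        # "age old-or-very-old AND smoking yes AND recent events yes -> high"
        rule = make_rule(
            toy_space, RiskLabel.HIGH,
            age=["old", "very old"], smoking=["yes"],
            heart_events_recently=["yes"],
        )
        chrom = toy_space.encode(rule)
        assert chrom.bits == (0, 0, 1, 1, 0, 0, 1, 0, 1, 0)
        assert chrom.cls is RiskLabel.HIGH

    def test_decode_drops_all_ones_segment(self, toy_space):
        chrom = Chromosome((1, 1, 1, 1, 1, 0, 1, 0, 1, 0), RiskLabel.LOW)
        rule = toy_space.decode(chrom)
        assert rule.selection("age") is None
        assert rule.n_features == 3

    def test_decode_readable_text(self, toy_space):
        chrom = Chromosome((0, 0, 1, 1, 0, 0, 1, 0, 1, 0), RiskLabel.HIGH)
        text = rule_to_text(toy_space.decode(chrom), toy_space)
        assert text == (
            "IF age is (old OR very old) AND smoking is (yes) AND "
            "heart_events_recently is (yes) THEN Risk is high-risk"
        )

    def test_all_zero_chromosome_is_invalid(self, toy_space):
        with pytest.raises(InvalidRuleError):
            toy_space.decode(Chromosome((0,) * 10, RiskLabel.LOW))

    def test_rule_without_relevant_feature_rejected(self):
        with pytest.raises(InvalidRuleError):
            FuzzyRule([LabelSelection("age", (0, 0, 0, 0))], RiskLabel.LOW)

    def test_mask_length_mismatch_rejected(self, toy_space):
        rule = FuzzyRule([LabelSelection("age", (1, 0))], RiskLabel.LOW)
        with pytest.raises(EncodingError):
            toy_space.encode(rule)

    def test_decode_encode_roundtrip_on_random_rules(self, toy_space):
        rng = np.random.default_rng(11)
        done = 0
        while done < 300:
            bits = tuple(int(b) for b in rng.integers(0, 2, toy_space.n_bits))
            chrom = Chromosome(bits, RiskLabel(int(rng.integers(3))))
            try:
                rule = toy_space.decode(chrom)
            except InvalidRuleError:
                continue
            again = toy_space.decode(toy_space.encode(rule))
            assert again.key() == rule.key()
            done += 1


class TestQualityMeasures:
    """Hand-checked compatibility/support/confidence on the toy partition."""

    @pytest.fixture
    def old_nonsmoker_rule(self, toy_space):
        return make_rule(toy_space, RiskLabel.MEDIUM,
                         age=["old"], smoking=["no"])

    def test_apc_full_match(self, table1, toy_space, old_nonsmoker_rule):
        # sigma1: age 74 (mu_old = 1), smoking no -> (1+1)/2
        assert apc(table1.cases[0], old_nonsmoker_rule, toy_space) == 1.0

    def test_apc_categorical_mismatch_contributes_zero(
        self, table1, toy_space, old_nonsmoker_rule
    ):
        # sigma3: age 74, smoking yes -> (1+0)/2
        assert apc(table1.cases[2], old_nonsmoker_rule, toy_space) == 0.5

    def test_apc_zero_when_nothing_matches(self, toy_space):
        rule = make_rule(toy_space, RiskLabel.LOW,
                         age=["young"], smoking=["yes"])
        case = PatientCase("x", {"age": 80.0, "smoking": "no"}, RiskLabel.LOW)
        assert apc(case, rule, toy_space) == 0.0

    def test_apc_missing_value_counts_in_denominator(self, toy_space):
        rule = make_rule(toy_space, RiskLabel.LOW,
                         age=["old"], smoking=["no"])
        case = PatientCase("x", {"age": 74.0}, RiskLabel.LOW)  # smoking absent
        assert apc(case, rule, toy_space) == 0.5

    def test_supp_gates_on_label(self, table1, toy_space, old_nonsmoker_rule):
        s1 = table1.cases[0]  # medium-risk, apc 1
        s4 = table1.cases[3]  # high-risk
        assert supp(s1, old_nonsmoker_rule, toy_space) == 1.0
        assert supp(s4, old_nonsmoker_rule, toy_space) == 0.0

    def test_support_and_confidence_match_printed_toy_values(
        self, table1, toy_space, old_nonsmoker_rule
    ):
        # the teaching example's medium rule: Support 0.339, Confidence 0.465
        assert support(old_nonsmoker_rule, table1, toy_space) == pytest.approx(
            0.339, abs=5e-4
        )
        assert confidence(old_nonsmoker_rule, table1, toy_space) == pytest.approx(
            0.465, abs=5e-4
        )

    def test_high_rule_matches_printed_toy_values(self, table1, toy_space):
        # male with recent events, middle-aged or older -> high: 0.324 / 0.455
        rule = make_rule(
            toy_space, RiskLabel.HIGH,
            age=["middle-aged", "old", "very old"], sex=["male"],
            heart_events_recently=["yes"],
        )
        assert support(rule, table1, toy_space) == pytest.approx(0.324, abs=5e-4)
        assert confidence(rule, table1, toy_space) == pytest.approx(0.455, abs=5e-4)

    def test_confidence_undefined_when_rule_never_fires(self, toy_space, table1):
        rule = make_rule(toy_space, RiskLabel.LOW, age=["young"])
        # every age in the fixture is >= 67, well above the young range
        with pytest.raises(UndefinedConfidenceError):
            confidence(rule, table1, toy_space)

    def test_confidence_never_below_support(self, table1, toy_space):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 100:
            bits = tuple(int(b) for b in rng.integers(0, 2, toy_space.n_bits))
            try:
                rule = toy_space.decode(
                    Chromosome(bits, RiskLabel(int(rng.integers(3))))
                )
                c = confidence(rule, table1, toy_space)
            except (InvalidRuleError, UndefinedConfidenceError):
                continue
            s = support(rule, table1, toy_space)
            assert 0.0 <= s <= c <= 1.0
            checked += 1

    def test_fitness_combination(self):
        assert combine_fitness(0.339, 0.465) == pytest.approx(0.402)
        assert combine_fitness(0, 0) == 0.0
        assert combine_fitness(1, 1) == 1.0


class TestRedundancy:
    def test_more_specific_rule_with_equal_support_is_redundant(
        self, table1, toy_space
    ):
        specific = make_rule(toy_space, RiskLabel.MEDIUM,
                             age=["old"], smoking=["no"])
        general = make_rule(toy_space, RiskLabel.MEDIUM,
                            age=["old", "very old"], smoking=["no"])
        s1 = support(specific, table1, toy_space)
        s2 = support(general, table1, toy_space)
        tol = abs(s1 - s2) + 1e-9
        assert is_redundant(specific, general, table1, toy_space, tol=tol)

    def test_differing_support_not_redundant(self, table1, toy_space):
        specific = make_rule(toy_space, RiskLabel.MEDIUM, age=["old"])
        general = make_rule(toy_space, RiskLabel.MEDIUM,
                            age=["old", "very old"])
        assert not is_redundant(specific, general, table1, toy_space, tol=1e-9)

    def test_different_consequents_never_redundant(self, table1, toy_space):
        r1 = make_rule(toy_space, RiskLabel.LOW, age=["old"])
        r2 = make_rule(toy_space, RiskLabel.HIGH, age=["old", "very old"])
        assert not is_redundant(r1, r2, table1, toy_space)

    def test_non_subset_masks_not_redundant(self, table1, toy_space):
        r1 = make_rule(toy_space, RiskLabel.LOW, smoking=["yes"])
        r2 = make_rule(toy_space, RiskLabel.LOW, smoking=["no"])
        assert not is_redundant(r1, r2, table1, toy_space, tol=1.0)


class TestVectorisedEvaluation:
    def test_population_stats_agree_with_scalar_path(self, table1, toy_space):
        matrices = FeatureMatrices(toy_space, table1)
        rng = np.random.default_rng(17)
        bits = rng.integers(0, 2, size=(64, toy_space.n_bits))
        from gfsrisk.ga import _segment_weights

        W = _segment_weights(toy_space)
        for cls in RISK_LEVELS:
            sup_v, conf_v, fit_v = matrices.population_stats(bits @ W, cls)
            for i in range(bits.shape[0]):
                chrom = Chromosome(tuple(int(b) for b in bits[i]), cls)
                try:
                    rule = toy_space.decode(chrom)
                except InvalidRuleError:
                    assert fit_v[i] == 0.0
                    continue
                stats = evaluate_rule(rule, table1, toy_space)
                assert sup_v[i] == pytest.approx(stats["support"], abs=1e-12)
                if stats["confidence"] is None:
                    assert fit_v[i] == 0.0
                else:
                    assert conf_v[i] == pytest.approx(
                        stats["confidence"], abs=1e-12
                    )
                    assert fit_v[i] == pytest.approx(
                        stats["fitness"], abs=1e-12
                    )

    def test_rule_firing_matches_scalar_firing_strength(self, table1, toy_space):
        from gfsrisk import firing_strength

        matrices = FeatureMatrices(toy_space, table1)
        rule = make_rule(toy_space, RiskLabel.MEDIUM,
                         age=["old"], smoking=["no"])
        beta = matrices.rule_firing(rule)
        for i, case in enumerate(table1):
            assert beta[i] == pytest.approx(
                firing_strength(rule, case, toy_space), abs=1e-12
            )

    def test_categorical_only_rule_apc_is_fraction(self, two_feature_dataset):
        space = RuleSpace(two_feature_dataset.schema, {})
        rule = make_rule(space, RiskLabel.HIGH, a=["yes"], b=["yes"])
        values = {apc(c, rule, space) for c in two_feature_dataset}
        assert values <= {0.0, 0.5, 1.0}
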