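"""APRIORI miner vs exhaustive enumeration, and the five metrics."""

import math
import random
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import as_itemsets, brute_force_itemsets, random_db
from hyporules.dichotomize import TransactionDB
from hyporules.errors import ParameterError
from hyporules.mining import (
    AssociationRule,
    RuleCounts,
    apriori_frequent_itemsets,
    confidence,
    conviction,
    coverage,
    generate_rules,
    leverage,
    lift,
    mine_rules,
)


@st.composite
def rule_counts(draw):
    n = draw(st.integers(min_value=1, max_value=200))
    n_a = draw(st.integers(min_value=1, max_value=n))
    n_b = draw(st.integers(min_value=1, max_value=n))
    # joint count bounded above by both margins and below by inclusion-exclusion
    n_ab = draw(st.integers(min_value=max(0, n_a + n_b - n), max_value=min(n_a, n_b)))
    return RuleCounts(N=n, nA=n_a, nB=n_b, nAB=n_ab)


class TestMetricExamples:
    """Frozen contingency examples from the published 25-tumor panel."""

    @pytest.mark.parametrize("counts,expected", [
        (RuleCounts(25, 11, 8, 8), Fraction(8, 11)),    # ≈ 0.73
        (RuleCounts(25, 16, 17, 15), Fraction(15, 16)),  # ≈ 0.94
        (RuleCounts(25, 5, 9, 5), Fraction(1)),
    ])
    def test_confidence(self, counts, expected):
        assert confidence(counts) == expected

    @pytest.mark.parametrize("counts,expected", [
        (RuleCounts(25, 14, 17, 14), Fraction(14, 17)),  # ≈ 0.82
        (RuleCounts(25, 11, 17, 11), Fraction(11, 17)),  # ≈ 0.65
        (RuleCounts(25, 11, 8, 8), Fraction(1)),
    ])
    def test_coverage(self, counts, expected):
        assert coverage(counts) == expected

    @pytest.mark.parametrize("counts,expected", [
        (RuleCounts(25, 8, 8, 8), Fraction(25, 8)),      # 3.125
        (RuleCounts(25, 14, 17, 14), Fraction(25, 17)),  # ≈ 1.47
        (RuleCounts(100, 20, 50, 10), Fraction(1)),      # independent
    ])
    def test_lift(self, counts, expected):
        assert lift(counts) == expected

    @pytest.mark.parametrize("counts,expected", [
        (RuleCounts(25, 8, 8, 8), Fraction(136, 625)),   # 0.2176 ≈ 0.22
        (RuleCounts(25, 7, 8, 7), Fraction(119, 625)),   # 0.1904 ≈ 0.19
        (RuleCounts(100, 20, 50, 10), Fraction(0)),
    ])
    def test_leverage(self, counts, expected):
        assert leverage(counts) == expected

    @pytest.mark.parametrize("counts,expected", [
        (RuleCounts(25, 11, 8, 8), Fraction(187, 100)),  # 1.87
        (RuleCounts(25, 8, 8, 8), Fraction(136, 25)),    # 5.44
        (RuleCounts(25, 14, 17, 14), Fraction(112, 25)),  # 4.48
    ])
    def test_smoothed_conviction(self, counts, expected):
        assert conviction(counts, "smoothed") == expected

    def test_classical_conviction_infinite_at_confidence_one(self):
        assert conviction(RuleCounts(25, 8, 8, 8), "classical") == math.inf

    def test_undefined_metric_errors(self):
        zero_a = RuleCounts(10, 0, 5, 0)
        with pytest.raises(ParameterError):
            confidence(zero_a)
        with pytest.raises(ParameterError):
            coverage(RuleCounts(10, 5, 0, 0))
        with pytest.raises(ParameterError):
            conviction(zero_a)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(rule_counts())
def test_metric_bounds(counts):
    assert 0 <= confidence(counts) <= 1
    assert 0 <= coverage(counts) <= 1
    assert lift(counts) >= 0
    assert Fraction(-1, 4) <= leverage(counts) <= Fraction(1, 4)
    smoothed = conviction(counts, "smoothed")
    assert 0 <= smoothed < math.inf


@settings(max_examples=300, deadline=None, derandomize=True)
@given(rule_counts())
def test_smoothed_conviction_below_classical_and_converges(counts):
    smoothed = conviction(counts, "smoothed")
    classical = conviction(counts, "classical")
    if counts.nAB < counts.nA:
        assert smoothed < classical
    # scaling all counts preserves classical conviction while the
    # smoothed variant approaches it from below
    big = RuleCounts(counts.N * 1000, counts.nA * 1000, counts.nB * 1000, counts.nAB * 1000)
    if counts.nAB < counts.nA and counts.nB < counts.N:
        assert conviction(big, "classical") == classical
        assert abs(float(conviction(big, "smoothed")) - float(classical)) <= float(
            classical
        ) * 1e-2


class TestApriori:
    def test_fixture_triple_itemset_count(self, fixture_db):
        itemsets = {
            s.items: s.count for s in apriori_frequent_itemsets(fixture_db, min_count=1)
        }
        assert itemsets[frozenset({"HIF1A=high", "PDK1=high", "PHD3=low"})] == 7

    def test_threshold_above_n_gives_empty(self, fixture_db):
        n = fixture_db.n_transactions
        assert apriori_frequent_itemsets(fixture_db, min_count=n + 1) == []

    def test_empty_database(self):
        db = TransactionDB(items=("a", "b"), transactions=())
        assert apriori_frequent_itemsets(db, min_count=1) == []

    def test_min_count_below_one_rejected(self, fixture_db):
        with pytest.raises(ParameterError):
            apriori_frequent_itemsets(fixture_db, min_count=0)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("min_count", [1, 2, 4])
    def test_matches_exhaustive_enumeration(self, seed, min_count):
        rng = random.Random(seed)
        db = random_db(rng, max_transactions=10, max_items=6)
        mined = {(s.items, s.count) for s in apriori_frequent_itemsets(db, min_count)}
        assert mined == brute_force_itemsets(db, min_count)

    def test_anti_monotonicity_on_fixture(self, fixture_db):
        itemsets = apriori_frequent_itemsets(fixture_db, min_count=1)
        counts = {s.items: s.count for s in itemsets}
        for items, count in counts.items():
            for sub, sub_count in counts.items():
                if sub < items:
                    assert sub_count >= count


class TestGenerateRules:
    def test_fixture_key_rules(self, fixture_db):
        itemsets = apriori_frequent_itemsets(fixture_db, min_count=1)
        rules = {
            r.pattern(): r for r in generate_rules(itemsets, fixture_db)
        }
        r1 = rules[(frozenset({"HIF1A=high"}), "HYPOXIA=high")]
        assert (r1.counts.nA, r1.counts.nAB) == (11, 8)
        r4 = rules[(frozenset({"HIF1A=high", "PHD3=low"}), "HYPOXIA=high")]
        assert (r4.counts.nA, r4.counts.nAB) == (8, 8)

    def test_antecedents_never_contain_hypoxia(self, fixture_db):
        for rule in mine_rules(fixture_db):
            assert not any(i.startswith("HYPOXIA=") for i in rule.antecedent)

    def test_non_cooccurring_pair_has_zero_confidence(self):
        db = TransactionDB(
            items=("a", "b"),
            transactions=(frozenset({"a"}), frozenset({"b"}), frozenset({"a"})),
        )
        itemsets = apriori_frequent_itemsets(db, min_count=1)
        rules = {r.pattern(): r for r in generate_rules(itemsets, db, consequent_domain=("b",))}
        rule = rules[(frozenset({"a"}), "b")]
        assert rule.counts.nAB == 0 and rule.confidence == 0

    def test_unknown_consequent_rejected(self, fixture_db):
        itemsets = apriori_frequent_itemsets(fixture_db, min_count=1)
        with pytest.raises(ParameterError, match="consequent"):
            generate_rules(itemsets, fixture_db, consequent_domain=("NOPE=high",))

    def test_rule_invariants_on_fixture(self, fixture_db):
        for rule in mine_rules(fixture_db):
            c = rule.counts
            assert 0 <= c.nAB <= min(c.nA, c.nB) <= c.N
            assert rule.consequent not in rule.antecedent

    def test_invalid_rule_construction(self):
        with pytest.raises(ParameterError):
            AssociationRule(frozenset(), "x", RuleCounts(5, 1, 1, 1))
        with pytest.raises(ParameterError):
            AssociationRule(frozenset({"x"}), "x", RuleCounts(5, 1, 1, 1))


def test_itemset_enumeration_agrees_with_rule_counts(fixture_db):
    """Joint counts used in rules equal direct database recounts."""
    for rule in mine_rules(fixture_db, min_count=4):
        direct = fixture_db.itemset_count(rule.antecedent | {rule.consequent})
        assert rule.counts.nAB == direct
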