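"""Apriori mining vs exhaustive enumeration; rule algebra."""

import pytest
from hypothesis import given, settings, strategies as st

from acumine import (
    Block,
    GeneratorConfig,
    MiningConfig,
    PrescriptionDataset,
    frequent_itemsets,
    generate,
    generate_rules,
)
from oracles import brute_force_itemsets, brute_force_rules


def _ds(*transactions):
    return PrescriptionDataset([frozenset(t) for t in transactions])


class TestFrequentItemsets:
    def test_hand_countable(self):
        ds = _ds({"A", "B"}, {"A", "B"}, {"A"}, {"B"})
        cfg = MiningConfig(min_support=0.5, min_item_frequency=0)
        got = frequent_itemsets(ds, cfg)
        assert got == {
            frozenset({"A"}): 0.75,
            frozenset({"B"}): 0.75,
            frozenset({"A", "B"}): 0.5,
        }

    def test_min_support_one_keeps_universal_itemsets(self):
        ds = _ds({"A", "B"}, {"A", "B", "C"})
        cfg = MiningConfig(min_support=1.0, min_item_frequency=0)
        got = frequent_itemsets(ds, cfg)
        assert set(got) == {
            frozenset({"A"}), frozenset({"B"}), frozenset({"A", "B"})
        }

    def test_item_frequency_floor_is_inclusive(self):
        ds = _ds(*([{"A", "B"}] * 10), *([{"B"}] * 5))
        cfg = MiningConfig(min_support=0.0, min_item_frequency=10)
        got = frequent_itemsets(ds, cfg)
        assert frozenset({"A"}) in got  # A appears exactly 10 times
        assert frozenset({"A", "B"}) in got

    def test_downward_closure(self):
        ds = generate(GeneratorConfig(seed=7))
        cfg = MiningConfig()
        got = frequent_itemsets(ds, cfg)
        for itemset, sup in got.items():
            for item in itemset:
                sub = itemset - {item}
                if sub:
                    assert sub in got
                    assert got[sub] >= sup

    def test_matches_bruteforce_on_corpus_synthetic(self):
        ds = generate(GeneratorConfig(seed=7))
        cfg = MiningConfig()
        got = frequent_itemsets(ds, cfg)
        expected = brute_force_itemsets(
            list(ds), cfg.min_support, cfg.min_item_frequency, cfg.max_itemset_size
        )
        assert got == pytest.approx(expected)

    @settings(max_examples=25)
    @given(
        st.lists(
            st.frozensets(st.sampled_from("ABCDEFG"), max_size=5),
            min_size=2,
            max_size=15,
        ),
        st.floats(min_value=0.1, max_value=0.9),
    )
    def test_matches_bruteforce_property(self, transactions, min_support):
        ds = PrescriptionDataset(list(transactions))
        cfg = MiningConfig(min_support=min_support, min_item_frequency=0,
                           max_itemset_size=4)
        got = frequent_itemsets(ds, cfg)
        expected = brute_force_itemsets(list(ds), min_support, 0, 4)
        assert got == pytest.approx(expected)


class TestRules:
    def test_arithmetic_from_hand_example(self):
        itemsets = {
            frozenset({"A"}): 0.5,
            frozenset({"B"}): 0.75,
            frozenset({"A", "B"}): 0.5,
        }
        cfg = MiningConfig(min_support=0.5, min_confidence=0.9,
                           min_item_frequency=0)
        rules = generate_rules(itemsets, cfg)
        (rule,) = rules
        assert rule.antecedent == frozenset({"A"})
        assert rule.consequent == frozenset({"B"})
        assert rule.confidence == pytest.approx(1.0)
        assert rule.lift == pytest.approx(4 / 3)

    def test_symmetric_perfect_pair_gives_both_directions(self):
        # A and B appear only together (but not in every transaction, so
        # the association is informative: lift = 2 > 1).
        ds = _ds(*([{"A", "B"}] * 10), *([{"C"}] * 10))
        cfg = MiningConfig(min_support=0.3, min_confidence=0.9,
                           min_item_frequency=0)
        rules = generate_rules(frequent_itemsets(ds, cfg), cfg)
        directed = {(tuple(sorted(r.antecedent)), tuple(sorted(r.consequent)))
                    for r in rules}
        assert (("A",), ("B",)) in directed and (("B",), ("A",)) in directed
        assert all(r.confidence == 1.0 for r in rules)

    def test_lift_symmetric_between_directions(self):
        ds = generate(GeneratorConfig(seed=13))
        cfg = MiningConfig(min_confidence=0.0, min_lift=0.0)
        rules = generate_rules(frequent_itemsets(ds, cfg), cfg)
        by_split = {(frozenset(r.antecedent), frozenset(r.consequent)): r.lift
                    for r in rules}
        for (a, c), lift in by_split.items():
            if (c, a) in by_split:
                assert lift == pytest.approx(by_split[(c, a)])

    def test_independent_items_produce_no_material_lift(self):
        # Two independent Bernoulli items at n=10,000: no rule should pass
        # a strict lift floor by more than sampling noise.
        cfg_gen = GeneratorConfig(
            n_transactions=10_000,
            marginal_targets={"A": 5000, "B": 5000},
            exact_marginals=False,
            seed=29,
        )
        ds = generate(cfg_gen)
        cfg = MiningConfig(min_support=0.05, min_confidence=0.0,
                           min_item_frequency=0, min_lift=0.0)
        rules = generate_rules(frequent_itemsets(ds, cfg), cfg)
        for r in rules:
            assert r.lift == pytest.approx(1.0, abs=0.05)

    def test_support_confidence_bounds(self):
        ds = generate(GeneratorConfig(seed=5))
        cfg = MiningConfig(min_confidence=0.5)
        for r in generate_rules(frequent_itemsets(ds, cfg), cfg):
            assert 0 <= r.support <= r.confidence <= 1
            assert r.lift > 0
            assert not (r.antecedent & r.consequent)

    def test_matches_bruteforce_rules(self):
        ds = generate(GeneratorConfig(seed=7))
        cfg = MiningConfig()
        itemsets = frequent_itemsets(ds, cfg)
        got = {(r.antecedent, r.consequent): (r.support, r.confidence, r.lift)
               for r in generate_rules(itemsets, cfg)}
        expected = {(a, c): (s, conf, lift)
                    for a, c, s, conf, lift in brute_force_rules(
                        brute_force_itemsets(list(ds), cfg.min_support,
                                             cfg.min_item_frequency,
                                             cfg.max_itemset_size),
                        cfg.min_confidence, cfg.min_lift)}
        assert set(got) == set(expected)
        for key in got:
            assert got[key] == pytest.approx(expected[key])

    def test_ranking_deterministic(self):
        ds = generate(GeneratorConfig(seed=19))
        cfg = MiningConfig(min_confidence=0.5)
        r1 = generate_rules(frequent_itemsets(ds, cfg), cfg)
        r2 = generate_rules(frequent_itemsets(ds, cfg), cfg)
        assert [(r.serialize(), r.support) for r in r1] == [
            (r.serialize(), r.support) for r in r2
        ]
        sups = [r.support for r in r1]
        assert sups == sorted(sups, reverse=True)
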