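"""Apriori frequent-itemset mining and association rule generation.

Classic level-wise apriori: size-k candidates are generated by joining
frequent (k-1)-itemsets sharing a (k-2)-prefix, pruned by downward closure
(every (k-1)-subset must itself be frequent), then counted by a scan over
the transactions. Support is the containing-transaction fraction of the
whole dataset. Rules are all ordered splits of each frequent itemset of
size >= 2 into a nonempty antecedent and consequent, kept when confidence
meets the floor and lift exceeds the (strict) lift floor.

The preset mirrors the published analysis: items restricted to acupoints
used at least 10 times, minimum support 15%, minimum confidence 90%,
lift > 1, itemsets up to size 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping

from .prescriptions import PrescriptionDataset, item_frequencies

__all__ = ["MiningConfig", "AssociationRule", "frequent_itemsets",
           "generate_rules", "write_rules_tsv"]


@dataclass(frozen=True)
class MiningConfig:
    min_support: float = 0.15
    min_confidence: float = 0.90
    min_item_frequency: int = 10  # inclusive absolute count floor
    max_itemset_size: int = 3
    min_lift: float = 1.0  # strict: lift must exceed this

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_support <= 1.0:
            raise ValueError("min_support must lie in [0, 1]")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValueError("min_confidence must lie in [0, 1]")
        if self.min_item_frequency < 0:
            raise ValueError("min_item_frequency must be >= 0")
        if self.max_itemset_size < 1:
            raise ValueError("max_itemset_size must be >= 1")
        if self.min_lift < 0:
            raise ValueError("min_lift must be >= 0")


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float
    lift: float

    def serialize(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return (tuple(sorted(self.antecedent)), tuple(sorted(self.consequent)))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        a = ",".join(sorted(self.antecedent))
        c = ",".join(sorted(self.consequent))
        return (f"[{a}] -> [{c}] support={self.support:.3f} "
                f"confidence={self.confidence:.3f} lift={self.lift:.3f}")


def frequent_itemsets(
    ds: PrescriptionDataset, cfg: MiningConfig
) -> dict[frozenset[str], float]:
    """All itemsets of size 1..max with support >= min_support."""
    n = len(ds)
    freqs = item_frequencies(ds)
    items = sorted(c for c, f in freqs.items() if f >= cfg.min_item_frequency)
    transactions = [t & frozenset(items) for t in ds]

    result: dict[frozenset[str], float] = {}
    # L1
    current = {}
    for item in items:
        sup = freqs[item] / n
        if sup >= cfg.min_support:
            current[(item,)] = sup
    result.update({frozenset(k): v for k, v in current.items()})

    k = 2
    while current and k <= cfg.max_itemset_size:
        frequent_prev = set(current)
        candidates = _join_candidates(sorted(current), frequent_prev)
        counts = dict.fromkeys(candidates, 0)
        if counts:
            for t in transactions:
                if len(t) < k:
                    continue
                for cand in counts:
                    if t.issuperset(cand):
                        counts[cand] += 1
        current = {
            cand: cnt / n for cand, cnt in counts.items()
            if cnt / n >= cfg.min_support
        }
        result.update({frozenset(cand): sup for cand, sup in current.items()})
        k += 1
    return result


def _join_candidates(
    prev: list[tuple[str, ...]], frequent_prev: set[tuple[str, ...]]
) -> list[tuple[str, ...]]:
    """(k-1)-prefix join with downward-closure pruning."""
    out = []
    for i, a in enumerate(prev):
        for b in prev[i + 1:]:
            if a[:-1] != b[:-1]:
                break  # prev is sorted, so prefixes no longer match
            cand = a + (b[-1],)
            if all(
                cand[:j] + cand[j + 1:] in frequent_prev for j in range(len(cand))
            ):
                out.append(cand)
    return out


def generate_rules(
    itemsets: Mapping[frozenset[str], float], cfg: MiningConfig
) -> list[AssociationRule]:
    """Rules from frequent itemsets passing the confidence and lift floors.

    Ranked by support descending, confidence descending, then the
    lexicographic serialization of (antecedent, consequent).
    """
    rules = []
    for itemset, sup in itemsets.items():
        if len(itemset) < 2:
            continue
        members = sorted(itemset)
        for r in range(1, len(members)):
            for ante in combinations(members, r):
                antecedent = frozenset(ante)
                consequent = itemset - antecedent
                sup_a = itemsets.get(antecedent)
                sup_c = itemsets.get(consequent)
                if sup_a is None or sup_c is None:
                    # Unreachable under downward closure; guards partial input.
                    continue
                confidence = sup / sup_a
                lift = confidence / sup_c
                if confidence >= cfg.min_confidence and lift > cfg.min_lift:
                    rules.append(
                        AssociationRule(antecedent, consequent, sup, confidence, lift)
                    )
    rules.sort(key=lambda r: (-r.support, -r.confidence, r.serialize()))
    return rules


def write_rules_tsv(rules: list[AssociationRule], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("antecedent\tconsequent\tsupport\tconfidence\tlift\n")
        for r in rules:
            a = ",".join(sorted(r.antecedent))
            c = ",".join(sorted(r.consequent))
            fh.write(f"{a}\t{c}\t{r.support:.6f}\t{r.confidence:.6f}\t{r.lift:.6f}\n")
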