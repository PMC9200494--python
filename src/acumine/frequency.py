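"""Descriptive frequency analysis: acupoint, meridian, region and
yin/yang aggregates with percentages.

Percentages are reported to the nearest integer with half-up rounding
(1.5 -> 2), matching the convention of the source tables. The yang and
yin shares use only the six yang and six yin channels; the governor and
conception vessels (DU, RN) and extra points (EX) are excluded from both
numerators — including DU among the yang channels would overstate the
yang share materially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .registry import Registry, REGIONS, MERIDIANS

__all__ = ["FrequencySummary", "summarize", "top_k", "round_half_up"]


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero toward +inf."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class GroupStat:
    count: int
    proportion: float
    n_acupoints: int


@dataclass(frozen=True)
class AcupointStat:
    count: int
    percent: int  # of transactions, half-up rounded


@dataclass(frozen=True)
class FrequencySummary:
    n_transactions: int
    grand_total: int
    n_acupoints: int
    per_acupoint: dict[str, AcupointStat]
    per_meridian: dict[str, GroupStat]
    per_region: dict[str, GroupStat]
    extra: tuple[int, int]  # (distinct extra points, total extra frequency)
    polarity_shares: dict[str, int]  # half-up integer percents of grand total

    def to_dict(self) -> dict:
        return {
            "n_transactions": self.n_transactions,
            "grand_total": self.grand_total,
            "n_acupoints": self.n_acupoints,
            "per_acupoint": {
                c: {"count": s.count, "percent": s.percent}
                for c, s in sorted(self.per_acupoint.items())
            },
            "per_meridian": {
                m: {"count": s.count, "proportion": s.proportion,
                    "n_acupoints": s.n_acupoints}
                for m, s in self.per_meridian.items()
            },
            "per_region": {
                r: {"count": s.count, "proportion": s.proportion,
                    "n_acupoints": s.n_acupoints}
                for r, s in self.per_region.items()
            },
            "extra": {"n_acupoints": self.extra[0], "total_frequency": self.extra[1]},
            "polarity_shares": dict(self.polarity_shares),
        }


def summarize(
    freqs: Mapping[str, int], registry: Registry, n_transactions: int
) -> FrequencySummary:
    """Aggregate per-code counts into meridian/region/polarity summaries.

    ``freqs`` maps canonical codes to the number of transactions containing
    each code; every code must resolve in the registry.
    """
    if n_transactions < 1:
        raise ValueError("n_transactions must be >= 1")
    for code in freqs:
        registry.lookup(code)

    used = {c: n for c, n in freqs.items() if n > 0}
    grand_total = sum(used.values())
    denom = grand_total if grand_total else 1

    per_acupoint = {
        c: AcupointStat(n, round_half_up(100 * n / n_transactions))
        for c, n in used.items()
    }

    def group_by(key) -> dict[str, GroupStat]:
        counts: dict[str, int] = {}
        distinct: dict[str, int] = {}
        for c, n in used.items():
            g = key(c)
            counts[g] = counts.get(g, 0) + n
            distinct[g] = distinct.get(g, 0) + 1
        return {
            g: GroupStat(counts[g], counts[g] / denom, distinct[g])
            for g in sorted(counts, key=lambda g: (-counts[g], g))
        }

    per_meridian = group_by(registry.meridian_of)
    per_region = group_by(registry.region_of)
    ex = per_meridian.get("EX")
    extra = (ex.n_acupoints, ex.count) if ex else (0, 0)

    polarity_totals: dict[str, int] = {"yang": 0, "yin": 0, "vessel": 0, "extra": 0}
    for m, stat in per_meridian.items():
        polarity_totals[MERIDIANS[m].polarity] += stat.count
    polarity_shares = {
        p: round_half_up(100 * t / denom) for p, t in polarity_totals.items()
    }

    return FrequencySummary(
        n_transactions=n_transactions,
        grand_total=grand_total,
        n_acupoints=len(used),
        per_acupoint=per_acupoint,
        per_meridian=per_meridian,
        per_region={r: per_region[r] for r in sorted(
            per_region, key=lambda r: (-per_region[r].count, r))},
        extra=extra,
        polarity_shares=polarity_shares,
    )


def top_k(freqs: Mapping[str, int], k: int) -> list[tuple[str, int]]:
    """The k most frequent codes, count descending, ties by ascending code."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]
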