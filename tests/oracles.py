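"""Independent brute-force oracles for itemset mining and Ward clustering.

These deliberately avoid the package's level-wise apriori and
Lance-Williams code paths: itemsets are enumerated exhaustively and merge
costs are recomputed from raw points at every step.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations

import numpy as np


def brute_force_itemsets(transactions, min_support, min_item_frequency, max_size):
    """Enumerate every itemset up to max_size and count it by scanning."""
    n = len(transactions)
    freqs = Counter(c for t in transactions for c in t)
    items = sorted(c for c, f in freqs.items() if f >= min_item_frequency)
    out = {}
    for k in range(1, max_size + 1):
        for combo in combinations(items, k):
            s = frozenset(combo)
            cnt = sum(1 for t in transactions if s <= t)
            if cnt / n >= min_support:
                out[s] = cnt / n
    return out


def brute_force_rules(itemsets, min_confidence, min_lift):
    """All qualifying antecedent->consequent splits of frequent itemsets."""
    out = []
    for itemset, sup in itemsets.items():
        if len(itemset) < 2:
            continue
        members = sorted(itemset)
        for r in range(1, len(members)):
            for ante in combinations(members, r):
                a = frozenset(ante)
                c = itemset - a
                if a not in itemsets or c not in itemsets:
                    continue
                conf = sup / itemsets[a]
                lift = conf / itemsets[c]
                if conf >= min_confidence and lift > min_lift:
                    out.append((a, c, sup, conf, lift))
    return out


def brute_force_ward(X, tie_rtol=1e-9):
    """Greedy Ward agglomeration recomputing delta-SSE from raw points.

    Returns (node_i, node_j, height, new_size) merges with the same node
    numbering and tie-break (lexicographically smallest pair of sorted
    leaf tuples) as the implementation, but costs come from direct
    within-cluster sum-of-squares differences, not a distance update.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]

    def sse(leaf_idx):
        pts = X[list(leaf_idx)]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    active = {i: (i,) for i in range(n)}
    merges = []
    next_node = n
    for _ in range(n - 1):
        best = None
        nodes = sorted(active)
        for ii, u in enumerate(nodes):
            for v in nodes[ii + 1:]:
                merged = tuple(sorted(active[u] + active[v]))
                cost = 2.0 * (sse(merged) - sse(active[u]) - sse(active[v]))
                key = tuple(sorted((active[u], active[v])))
                if best is None or cost < best[0] * (1 - tie_rtol) - 1e-12:
                    best = (cost, key, u, v)
                elif cost <= best[0] * (1 + tie_rtol) + 1e-12 and key < best[1]:
                    best = (min(cost, best[0]), key, u, v)
        cost, _, u, v = best
        merged = tuple(sorted(active[u] + active[v]))
        merges.append((min(u, v), max(u, v), float(np.sqrt(max(cost, 0.0))),
                       len(merged)))
        del active[u], active[v]
        active[next_node] = merged
        next_node += 1
    return merges
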