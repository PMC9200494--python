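"""Acupoint co-occurrence network.

The edge weight between two acupoints is the number of prescriptions
containing both; the network stage keeps edges at or above a minimum
weight (the pipeline preset uses 30) and ranks them by weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx

from .prescriptions import PrescriptionDataset

__all__ = ["CooccurrenceEdge", "pair_counts", "threshold_network",
           "to_graph", "write_edge_tsv", "write_dot"]


@dataclass(frozen=True)
class CooccurrenceEdge:
    """Unordered acupoint pair with its joint transaction count."""

    pair: tuple[str, str]  # lexicographically ordered
    weight: int

    def __post_init__(self) -> None:
        a, b = self.pair
        if a >= b:
            raise ValueError("pair must be distinct and lexicographically ordered")


def pair_counts(ds: PrescriptionDataset) -> list[CooccurrenceEdge]:
    """All acupoint pairs co-occurring in at least one prescription."""
    counts: dict[tuple[str, str], int] = {}
    for t in ds:
        for a, b in combinations(sorted(t), 2):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return [CooccurrenceEdge(p, w) for p, w in sorted(counts.items())]


def threshold_network(
    edges: list[CooccurrenceEdge], min_weight: int
) -> tuple[list[CooccurrenceEdge], set[str]]:
    """Keep edges with weight >= min_weight; nodes are surviving endpoints.

    Edges come back ranked by weight descending, then lexicographic pair.
    """
    if min_weight < 1:
        raise ValueError("min_weight must be >= 1")
    kept = sorted(
        (e for e in edges if e.weight >= min_weight),
        key=lambda e: (-e.weight, e.pair),
    )
    nodes = {c for e in kept for c in e.pair}
    return kept, nodes


def to_graph(edges: list[CooccurrenceEdge]) -> nx.Graph:
    g = nx.Graph()
    for e in edges:
        g.add_edge(*e.pair, weight=e.weight)
    return g


def write_edge_tsv(edges: list[CooccurrenceEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("code_a\tcode_b\tweight\n")
        for e in edges:
            fh.write(f"{e.pair[0]}\t{e.pair[1]}\t{e.weight}\n")


def write_dot(edges: list[CooccurrenceEdge], path: str | Path) -> None:
    """Minimal undirected DOT export with weight attributes."""
    lines = ["graph cooccurrence {"]
    for e in edges:
        lines.append(f'  "{e.pair[0]}" -- "{e.pair[1]}" [weight={e.weight}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
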