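"""Agglomerative clustering of acupoints: Euclidean distance, Ward linkage.

Acupoints are represented by their binary incidence vectors over the
prescriptions (1 where the point appears). Agglomeration starts from
singletons and at each step merges the cluster pair whose fusion least
increases the within-cluster sum of squares; inter-cluster distances are
maintained with the Lance-Williams recurrence for Ward linkage. Heights
follow the common dendrogram convention d = sqrt(2 * delta-SSE), so the
height of a two-singleton merge is their Euclidean distance.

Binary data produces many exactly tied merge costs; ties are broken by the
lexicographically smallest pair of clusters (clusters ordered by their
sorted leaf index tuples), which makes the tree fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .prescriptions import PrescriptionDataset, item_frequencies

__all__ = ["Dendrogram", "ClusterAssignment", "occurrence_matrix",
           "ward_linkage", "cut_tree", "to_newick", "write_merge_tsv"]

# Relative tolerance for treating two merge costs as tied; Lance-Williams
# updates and direct sum-of-squares computation agree to float precision.
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree over ordered leaves.

    ``merges`` holds (node_i, node_j, height, new_size) records; leaves are
    nodes 0..n-1 and merge m creates node n+m (the scipy linkage
    convention).
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError("a binary dendrogram has exactly n-1 merges")
        heights = [m[2] for m in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be nondecreasing")

    @property
    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def linkage_matrix(self) -> np.ndarray:
        """The merge table as a scipy-style (n-1, 4) linkage array."""
        return np.array([list(m) for m in self.merges], dtype=float)


@dataclass(frozen=True)
class ClusterAssignment:
    k: int
    assignment: dict[str, int]  # code -> 1..k

    def clusters(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.k)]
        for code, label in self.assignment.items():
            out[label - 1].add(code)
        return out


def occurrence_matrix(
    ds: PrescriptionDataset, min_item_frequency: int = 0
) -> tuple[np.ndarray, list[str]]:
    """Binary acupoint-by-prescription matrix, rows lexicographic.

    Rows are restricted to acupoints whose frequency is at least
    ``min_item_frequency`` (inclusive).
    """
    freqs = item_frequencies(ds)
    codes = sorted(c for c, f in freqs.items() if f >= min_item_frequency)
    if not codes:
        raise ValueError("no acupoint passes the frequency filter")
    idx = {c: i for i, c in enumerate(codes)}
    X = np.zeros((len(codes), len(ds)), dtype=float)
    for j, t in enumerate(ds):
        for code in t:
            if code in idx:
                X[idx[code], j] = 1.0
    return X, codes


def ward_linkage(X: np.ndarray, leaf_names: list[str] | None = None) -> Dendrogram:
    """Ward's minimum-variance agglomeration of the rows of X."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to cluster")
    names = tuple(leaf_names) if leaf_names is not None else tuple(
        str(i) for i in range(n)
    )
    if len(names) != n:
        raise ValueError("leaf_names length mismatch")

    # Squared pairwise distances; D2 == 2 * delta-SSE for the merge.
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    d2: dict[frozenset[int], float] = {}
    active: dict[int, tuple[int, tuple[int, ...]]] = {
        i: (1, (i,)) for i in range(n)
    }  # node -> (size, sorted leaf tuple)
    for i in range(n):
        for j in range(i + 1, n):
            d2[frozenset((i, j))] = sq[i, j]

    merges: list[tuple[int, int, float, int]] = []
    next_node = n
    for _ in range(n - 1):
        best = None
        nodes = sorted(active)
        for ii, u in enumerate(nodes):
            for v in nodes[ii + 1:]:
                cost = d2[frozenset((u, v))]
                pair_key = tuple(sorted((active[u][1], active[v][1])))
                if best is None or cost < best[0] * (1 - _TIE_RTOL) - 1e-12:
                    best = (cost, pair_key, u, v)
                elif cost <= best[0] * (1 + _TIE_RTOL) + 1e-12 and pair_key < best[1]:
                    best = (min(cost, best[0]), pair_key, u, v)
        cost, _, u, v = best
        nu, leaves_u = active[u]
        nv, leaves_v = active[v]
        new_size = nu + nv
        height = float(np.sqrt(max(cost, 0.0)))
        merges.append((min(u, v), max(u, v), height, new_size))
        # Lance-Williams update for Ward on squared distances.
        for w in active:
            if w in (u, v):
                continue
            nw = active[w][0]
            duw = d2.pop(frozenset((u, w)))
            dvw = d2.pop(frozenset((v, w)))
            d2[frozenset((next_node, w))] = (
                (nu + nw) * duw + (nv + nw) * dvw - nw * cost
            ) / (new_size + nw)
        d2.pop(frozenset((u, v)))
        del active[u], active[v]
        active[next_node] = (new_size, tuple(sorted(leaves_u + leaves_v)))
        next_node += 1

    return Dendrogram(names, tuple(merges))


def cut_tree(d: Dendrogram, k: int) -> ClusterAssignment:
    """Cut into k clusters by removing the k-1 highest (last) merges.

    Cluster labels are assigned 1..k in order of each cluster's
    lexicographically smallest leaf name.
    """
    n = len(d.leaves)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m, (i, j, _, _) in enumerate(d.merges[: n - k]):
        node = n + m
        parent[find(i)] = node
        parent[find(j)] = node

    groups: dict[int, set[str]] = {}
    for leaf_idx, name in enumerate(d.leaves):
        groups.setdefault(find(leaf_idx), set()).add(name)
    ordered = sorted(groups.values(), key=min)
    assignment = {
        name: label for label, members in enumerate(ordered, start=1)
        for name in members
    }
    return ClusterAssignment(k=k, assignment=assignment)


def to_newick(d: Dendrogram) -> str:
    """Newick serialization; branch lengths are height differences."""
    n = len(d.leaves)
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for m, (i, j, h, _) in enumerate(d.merges):
        node = n + m
        height[node] = h
        children[node] = (i, j)

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - height[node]
        if node < n:
            return f"{d.leaves[node]}:{bl:.6g}"
        left, right = children[node]
        h = height[node]
        return f"({render(left, h)},{render(right, h)}):{bl:.6g}"

    root = n + len(d.merges) - 1
    left, right = children[root]
    h = height[root]
    return f"({render(left, h)},{render(right, h)});"


def write_merge_tsv(d: Dendrogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\theight\tnew_size\n")
        for i, j, h, s in d.merges:
            fh.write(f"{i}\t{j}\t{h:.6f}\t{s}\n")
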