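"""Seeded synthetic prescription generator.

The raw 42-prescription transaction table behind the published corpus is
not deposited; only per-acupoint marginal counts are printed. This module
generates transaction datasets with those marginals (or any user-supplied
targets) plus configurable pairwise co-occurrence structure, so that every
downstream stage — frequency summaries, co-occurrence networks, apriori
mining, Ward clustering — is testable end to end.

Two modes:

* ``exact_marginals=True`` — each code is placed in a uniform random subset
  of transactions of exactly its target size; block coupling then relocates
  occurrences of block members into transactions holding the block anchor,
  preserving every per-code margin (margin-preserving relocation on the
  binary incidence matrix). The boost weight in [0, 1] sets the fraction of
  possible relocations performed; at 1.0 the smaller member's occurrences
  become a subset of the anchor's, so the pair's joint count equals the
  smaller target.
* ``exact_marginals=False`` — independent Bernoulli inclusion with
  probability target/n per transaction, plus a latent per-transaction block
  indicator with probability equal to the boost that forces joint inclusion
  of all block members. Marginals are inflated accordingly:
  P(member present) = p + boost - p*boost.

All randomness flows from one integer seed through one numpy generator;
the same seed and config reproduce the dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .prescriptions import PrescriptionDataset
from .registry import load_registry

__all__ = ["GeneratorConfig", "GenerationInfo", "generate", "generate_with_info"]


@dataclass(frozen=True)
class Block:
    """A set of codes whose co-occurrence is boosted."""

    members: tuple[str, ...]
    boost: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.boost <= 1.0:
            raise ValueError("block boost must lie in [0, 1]")
        if len(self.members) < 2:
            raise ValueError("a block needs at least 2 members")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate member in block")


@dataclass
class GeneratorConfig:
    """Configuration for :func:`generate`.

    Defaults emulate the published corpus: 42 transactions over the 141
    registry acupoints with the printed marginal counts.
    """

    n_transactions: int = 42
    marginal_targets: dict[str, int] | None = None
    blocks: list[Block] = field(default_factory=list)
    exact_marginals: bool = True
    seed: int = 0

    def resolved_targets(self) -> dict[str, int]:
        if self.marginal_targets is None:
            return load_registry().frequencies()
        return dict(self.marginal_targets)

    def validate(self) -> dict[str, int]:
        if self.n_transactions < 1:
            raise ValueError("n_transactions must be positive")
        targets = self.resolved_targets()
        for code, t in targets.items():
            if not 0 <= t <= self.n_transactions:
                raise ValueError(
                    f"target for {code} is {t}, outside [0, {self.n_transactions}]"
                )
        for block in self.blocks:
            missing = [m for m in block.members if m not in targets]
            if missing:
                raise ValueError(f"block members missing from targets: {missing}")
        return targets


@dataclass
class GenerationInfo:
    """Bookkeeping emitted alongside a generated dataset.

    ``block_pair_counts`` holds the realized joint transaction count for
    every within-block pair, computed directly on the incidence matrix
    during generation; downstream co-occurrence counting can be checked
    against it.
    """

    item_counts: dict[str, int]
    block_pair_counts: dict[tuple[str, str], int]


def _exact_matrix(
    targets: dict[str, int], cfg: GeneratorConfig, rng: np.random.Generator,
    codes: list[str],
) -> np.ndarray:
    n = cfg.n_transactions
    X = np.zeros((len(codes), n), dtype=bool)
    for i, code in enumerate(codes):
        t = targets[code]
        if t:
            X[i, rng.choice(n, size=t, replace=False)] = True
    idx = {c: i for i, c in enumerate(codes)}
    for block in cfg.blocks:
        # Anchor = member with the largest target (ties by code, for
        # determinism); other members are pulled into its transactions.
        members = sorted(block.members, key=lambda c: (-targets[c], c))
        a = idx[members[0]]
        for code in members[1:]:
            b = idx[code]
            movable = np.flatnonzero(X[b] & ~X[a])
            vacant = np.flatnonzero(X[a] & ~X[b])
            n_moves = int(np.floor(block.boost * min(len(movable), len(vacant)) + 0.5))
            if n_moves == 0:
                continue
            src = rng.choice(movable, size=n_moves, replace=False)
            dst = rng.choice(vacant, size=n_moves, replace=False)
            X[b, src] = False
            X[b, dst] = True
    return X


def _bernoulli_matrix(
    targets: dict[str, int], cfg: GeneratorConfig, rng: np.random.Generator,
    codes: list[str],
) -> np.ndarray:
    n = cfg.n_transactions
    p = np.array([targets[c] / n for c in codes])
    X = rng.random((len(codes), n)) < p[:, None]
    idx = {c: i for i, c in enumerate(codes)}
    for block in cfg.blocks:
        latent = rng.random(n) < block.boost
        for code in block.members:
            X[idx[code], latent] = True
    return X


def generate_with_info(cfg: GeneratorConfig) -> tuple[PrescriptionDataset, GenerationInfo]:
    """Generate a dataset and its generation bookkeeping."""
    targets = cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    codes = sorted(targets)
    if cfg.exact_marginals:
        X = _exact_matrix(targets, cfg, rng, codes)
    else:
        X = _bernoulli_matrix(targets, cfg, rng, codes)
    transactions = [
        frozenset(codes[i] for i in np.flatnonzero(X[:, j]))
        for j in range(cfg.n_transactions)
    ]
    pair_counts: dict[tuple[str, str], int] = {}
    idx = {c: i for i, c in enumerate(codes)}
    for block in cfg.blocks:
        members = sorted(block.members)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                pair_counts[(a, b)] = int(np.sum(X[idx[a]] & X[idx[b]]))
    info = GenerationInfo(
        item_counts={c: int(X[idx[c]].sum()) for c in codes},
        block_pair_counts=pair_counts,
    )
    ds = PrescriptionDataset(
        transactions, [f"S{j + 1}" for j in range(cfg.n_transactions)]
    )
    return ds, info


def generate(cfg: GeneratorConfig) -> PrescriptionDataset:
    """Generate a synthetic prescription dataset (see module docstring)."""
    return generate_with_info(cfg)[0]
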