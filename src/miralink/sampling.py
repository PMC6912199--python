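"""Positive-unlabeled sample space and per-disease five-fold CV splits.

Known associations are the positives; every other (disease, miRNA) cell of
the m x h grid is unlabeled.  Because true-but-unknown associations are
assumed to be rare relative to the grid, negatives are drawn uniformly
without replacement from the unlabeled pairs at a 1:1 ratio to the
positives.

For cross-validation each disease's positives are shuffled (seeded) and
dealt round-robin into five folds; the fold-f training network removes
exactly the fold-f edges of every disease, so held-out associations are
invisible to walk generation, feature building and training alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .similarity import AssociationNetwork

__all__ = [
    "SampleSpace",
    "FoldPlan",
    "enumerate_unlabeled",
    "sample_negatives",
    "make_disease_folds",
    "build_sample_space",
]

Pair = tuple[str, str]


@dataclass
class SampleSpace:
    positives: set[Pair]
    unlabeled: set[Pair]
    negatives: set[Pair]
    seed: int

    def __post_init__(self) -> None:
        if self.positives & self.unlabeled:
            raise ValueError("positives and unlabeled pairs overlap")
        if not self.negatives <= self.unlabeled:
            raise ValueError("negatives must be drawn from the unlabeled pairs")


@dataclass
class FoldPlan:
    """Five disjoint positive-pair subsets for one disease."""

    disease: str
    folds: list[list[Pair]] = field(default_factory=list)
    seed: int = 0

    def held_out(self, fold: int) -> set[Pair]:
        return set(self.folds[fold])


def enumerate_unlabeled(net: AssociationNetwork) -> set[Pair]:
    """All grid cells that are not known associations (m*h - |edges|)."""
    return {
        (d, m) for d in net.diseases for m in net.mirnas if (d, m) not in net.edges
    }


def sample_negatives(unlabeled: set[Pair], k: int, seed: int) -> set[Pair]:
    """Uniform sample of k unlabeled pairs without replacement (seeded)."""
    if k > len(unlabeled):
        raise ValueError(f"requested {k} negatives from {len(unlabeled)} unlabeled pairs")
    pool = sorted(unlabeled)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=k, replace=False)
    return {pool[i] for i in idx}


def make_disease_folds(
    net: AssociationNetwork, disease: str, seed: int, n_folds: int = 5
) -> FoldPlan:
    """Seeded shuffle + round-robin split of one disease's positives.

    Diseases with fewer than ``n_folds`` positives still get a plan (some
    folds empty); fold sizes differ by at most one.
    """
    if disease not in net.diseases:
        raise ValueError(f"unknown disease {disease!r}")
    positives = sorted((disease, m) for d, m in net.edges if d == disease)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    folds: list[list[Pair]] = [[] for _ in range(n_folds)]
    for rank, idx in enumerate(order):
        folds[rank % n_folds].append(positives[idx])
    return FoldPlan(disease, folds, seed)


def build_sample_space(net: AssociationNetwork, seed: int, ratio: float = 1.0) -> SampleSpace:
    """Positives, unlabeled pairs and a 1:1 (by default) negative sample."""
    unlabeled = enumerate_unlabeled(net)
    k = min(int(round(ratio * len(net.edges))), len(unlabeled))
    negatives = sample_negatives(unlabeled, k, seed)
    return SampleSpace(set(net.edges), unlabeled, negatives, seed)
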