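"""Bilayer-network construction: disease and miRNA similarity matrices.

Disease similarity (DS) is derived from a functional gene network whose
edges carry log-likelihood scores (LLS).  For two diseases with associated
gene sets S(di), S(dj),

    DS(di, dj) = [ sum_{g in S(di)} LLS(g, S(dj))
                 + sum_{g in S(dj)} LLS(g, S(di)) ] / (|S(di)| + |S(dj)|)

and 0 when both gene sets are empty.  LLS(g, S) aggregates the edge scores
from gene g into the set S; the default aggregation is the sum over edges
present in the network ("max" is available as an alternative).

miRNA similarity (RS) is a weighted combination of four components:
target sharing (RST), family co-membership (RSF), cluster co-membership
(RSC) and a precomputed disease-derived similarity matrix (RSD):

    RS = alpha*RST + beta*RSF + gamma*RSC + delta*RSD

with default weights (0.2, 0.1, 0.2, 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GeneNetwork",
    "AssociationNetwork",
    "SimilarityMatrix",
    "SimilarityWeights",
    "lls_gene_to_set",
    "compute_ds_matrix",
    "compute_rst_matrix",
    "membership_similarity",
    "combine_rs_matrix",
]


class GeneNetwork:
    """Undirected gene-gene functional network with non-negative LLS weights.

    Self-edges are ignored; duplicate edges keep the last weight seen.
    """

    def __init__(self, edges: Iterable[tuple[str, str, float]] = ()):
        self._adj: dict[str, dict[str, float]] = {}
        for a, b, w in edges:
            self.add_edge(a, b, w)

    def add_edge(self, a: str, b: str, lls: float) -> None:
        if a == b:
            return
        lls = float(lls)
        if lls < 0:
            raise ValueError(f"LLS must be non-negative, got {lls} for ({a}, {b})")
        self._adj.setdefault(a, {})[b] = lls
        self._adj.setdefault(b, {})[a] = lls

    def neighbors(self, g: str) -> Mapping[str, float]:
        return self._adj.get(g, {})

    def weight(self, a: str, b: str) -> float:
        return self._adj.get(a, {}).get(b, 0.0)

    @property
    def n_genes(self) -> int:
        return len(self._adj)

    def __contains__(self, g: str) -> bool:
        return g in self._adj


@dataclass
class AssociationNetwork:
    """Bipartite disease-miRNA association network.

    ``diseases`` and ``mirnas`` are the ordered node lists (lexicographic
    by convention); ``edges`` the set of known associations.  Duplicate
    records are dropped on construction.
    """

    diseases: list[str]
    mirnas: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        d, m = set(self.diseases), set(self.mirnas)
        self.edges = set(self.edges)
        for dis, mir in self.edges:
            if dis not in d or mir not in m:
                raise ValueError(
                    f"edge ({dis}, {mir}) references unknown disease or miRNA"
                )

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "AssociationNetwork":
        edges = set(edges)
        diseases = sorted({d for d, _ in edges})
        mirnas = sorted({m for _, m in edges})
        return cls(diseases, mirnas, edges)

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)

    def mirnas_of(self, disease: str) -> list[str]:
        return sorted(m for d, m in self.edges if d == disease)

    def without_edges(self, removed: Iterable[tuple[str, str]]) -> "AssociationNetwork":
        """Copy of the network with the given edges removed (nodes kept)."""
        removed = set(removed)
        return AssociationNetwork(
            list(self.diseases), list(self.mirnas), self.edges - removed
        )


@dataclass
class SimilarityMatrix:
    """Dense symmetric similarity matrix with an ordered entity-ID list."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity matrix contains non-finite entries")
        if np.max(np.abs(self.values - self.values.T), initial=0.0) > 1e-9:
            raise ValueError("similarity matrix is not symmetric within 1e-9")
        self._index = {e: i for i, e in enumerate(self.ids)}

    def row(self, entity: str) -> np.ndarray:
        try:
            return self.values[self._index[entity]]
        except KeyError:
            raise KeyError(f"unknown entity {entity!r}") from None

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self._index[a], self._index[b]])

    def subset(self, ids: list[str]) -> "SimilarityMatrix":
        """Reindexed copy restricted to the given IDs (must all be present)."""
        missing = [e for e in ids if e not in self._index]
        if missing:
            raise KeyError(f"IDs absent from similarity matrix: {missing}")
        idx = [self._index[e] for e in ids]
        return SimilarityMatrix(list(ids), self.values[np.ix_(idx, idx)])


@dataclass(frozen=True)
class SimilarityWeights:
    """Weights (alpha, beta, gamma, delta) for RST/RSF/RSC/RSD combination."""

    alpha: float = 0.2
    beta: float = 0.1
    gamma: float = 0.2
    delta: float = 0.5

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def lls_gene_to_set(
    g: str, genes: Iterable[str], net: GeneNetwork, aggregation: str = "sum"
) -> float:
    """LLS between a single gene and a gene set.

    Sums (default) or maximises the network edge scores from ``g`` to the
    members of ``genes`` that are network neighbours of ``g``.  Returns 0
    when no such edge exists.
    """
    nbrs = net.neighbors(g)
    scores = [nbrs[x] for x in genes if x in nbrs]
    if not scores:
        return 0.0
    if aggregation == "sum":
        return float(sum(scores))
    if aggregation == "max":
        return float(max(scores))
    raise ValueError(f"unknown aggregation {aggregation!r}")


def compute_ds_matrix(
    disease_genes: Mapping[str, set[str]],
    net: GeneNetwork,
    diseases: list[str],
    aggregation: str = "sum",
) -> SimilarityMatrix:
    """Disease-similarity matrix over the given ordered disease list.

    Entry (i, j) averages the bidirectional gene-to-set LLS sums by the
    combined gene-set size; 0 when both gene sets are empty.
    """
    if not diseases:
        raise ValueError("disease list must be non-empty")
    unknown = [d for d in diseases if d not in disease_genes]
    if unknown:
        raise ValueError(f"diseases missing from the disease-gene map: {unknown}")

    m = len(diseases)
    sets = {d: set(disease_genes[d]) for d in diseases}
    # Precompute per-disease {gene: LLS(g, S(d))} maps over genes adjacent
    # to at least one member of S(d); makes the double loop O(m^2) lookups.
    values = np.zeros((m, m))
    for i, di in enumerate(diseases):
        for j in range(i, m):
            dj = diseases[j]
            si, sj = sets[di], sets[dj]
            denom = len(si) + len(sj)
            if denom == 0:
                continue
            total = sum(lls_gene_to_set(g, sj, net, aggregation) for g in si)
            total += sum(lls_gene_to_set(g, si, net, aggregation) for g in sj)
            values[i, j] = values[j, i] = total / denom
    return SimilarityMatrix(list(diseases), values)


def compute_rst_matrix(
    targets: Mapping[str, set[str]], mirnas: list[str], normalize: bool = True
) -> SimilarityMatrix:
    """Target-sharing similarity: off-diagonal counts of shared targets.

    With ``normalize`` the counts are divided by the global maximum
    off-diagonal count, giving entries in [0, 1] commensurate with the
    other RS components.  The diagonal is forced to 0.  miRNAs absent from
    the target map contribute empty target sets.
    """
    if not mirnas:
        raise ValueError("miRNA list must be non-empty")
    h = len(mirnas)
    sets = [frozenset(targets.get(r, ())) for r in mirnas]
    values = np.zeros((h, h))
    for i in range(h):
        for j in range(i + 1, h):
            c = len(sets[i] & sets[j])
            values[i, j] = values[j, i] = c
    if normalize:
        top = values.max()
        if top > 0:
            values /= top
    return SimilarityMatrix(list(mirnas), values)


def membership_similarity(
    groups: Mapping[str, set[str]], mirnas: list[str]
) -> SimilarityMatrix:
    """Binary co-membership similarity (used for both family and cluster).

    Entry (i, j) is 1 when the two miRNAs share at least one group.  The
    diagonal is 1 for annotated miRNAs and 0 for unannotated ones.
    """
    h = len(mirnas)
    sets = [frozenset(groups.get(r, ())) for r in mirnas]
    values = np.zeros((h, h))
    for i in range(h):
        for j in range(i, h):
            values[i, j] = values[j, i] = 1.0 if sets[i] & sets[j] else 0.0
    return SimilarityMatrix(list(mirnas), values)


def combine_rs_matrix(
    rst: SimilarityMatrix,
    rsf: SimilarityMatrix,
    rsc: SimilarityMatrix,
    rsd: SimilarityMatrix,
    weights: SimilarityWeights = SimilarityWeights(),
) -> SimilarityMatrix:
    """Elementwise weighted combination of the four miRNA similarity parts."""
    ids = rst.ids
    for other in (rsf, rsc, rsd):
        if other.ids != ids:
            raise ValueError("similarity matrices have mismatched ID orderings")
    values = (
        weights.alpha * rst.values
        + weights.beta * rsf.values
        + weights.gamma * rsc.values
        + weights.delta * rsd.values
    )
    return SimilarityMatrix(list(ids), values)
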