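"""Plain-text TSV readers and writers for every pipeline input and output.

Dialects:

* gene network      -- ``gene1<TAB>gene2<TAB>lls`` (no header)
* membership tables -- two columns ``entity<TAB>group`` (no header)
* associations      -- ``disease<TAB>mirna`` (no header)
* similarity matrix -- TSV with an ID header row and an ID first column
* embeddings        -- word2vec text: first line ``|V| n`` then one
                       ``id v1 ... vn`` line per node
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .similarity import AssociationNetwork, GeneNetwork, SimilarityMatrix

__all__ = [
    "load_gene_network",
    "load_membership_map",
    "load_associations",
    "load_similarity_matrix",
    "save_similarity_matrix",
    "save_embeddings",
    "load_embeddings",
    "save_walks",
]


def load_gene_network(path: str | Path) -> GeneNetwork:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene1", "gene2", "lls"])
    net = GeneNetwork()
    for a, b, w in df.itertuples(index=False):
        net.add_edge(str(a), str(b), float(w))
    return net


def load_membership_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column table (entity, group) into a dict of group-ID sets.

    Serves the disease->gene, miRNA->target, miRNA->family and
    miRNA->cluster tables alike.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["entity", "group"])
    out: dict[str, set[str]] = {}
    for e, g in df.itertuples(index=False):
        out.setdefault(str(e), set()).add(str(g))
    return out


def load_associations(path: str | Path) -> AssociationNetwork:
    """Disease-miRNA association edge list; duplicates are dropped."""
    df = pd.read_csv(path, sep="\t", header=None, names=["disease", "mirna"])
    edges = {(str(d), str(m)) for d, m in df.itertuples(index=False)}
    return AssociationNetwork.from_edges(edges)


def load_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise ValueError(f"{path}: row and column IDs differ")
    return SimilarityMatrix(ids, df.to_numpy(dtype=float))


def save_similarity_matrix(mat: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(mat.values, index=mat.ids, columns=mat.ids).to_csv(path, sep="\t")


def save_embeddings(ids: list[str], vectors: np.ndarray, path: str | Path) -> None:
    vectors = np.asarray(vectors)
    with open(path, "w") as fh:
        fh.write(f"{len(ids)} {vectors.shape[1]}\n")
        for node, row in zip(ids, vectors):
            fh.write(node + " " + " ".join(repr(float(v)) for v in row) + "\n")


def load_embeddings(path: str | Path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        n, dim = map(int, fh.readline().split())
        ids, rows = [], []
        for line in fh:
            parts = line.split()
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    vectors = np.array(rows, dtype=float)
    if vectors.shape != (n, dim):
        raise ValueError(f"{path}: header promises {(n, dim)}, got {vectors.shape}")
    return ids, vectors


def save_walks(walks: list[list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for walk in walks:
            fh.write(" ".join(walk) + "\n")


def save_memberships(mapping: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for entity in sorted(mapping):
            for group in sorted(mapping[entity]):
                fh.write(f"{entity}\t{group}\n")
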