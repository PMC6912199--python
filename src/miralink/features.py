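"""Disease-miRNA pair feature vectors.

Two feature families feed the classifiers:

* similarity-based -- [DS row of the disease || RS row of the miRNA],
  length m + h (913 at the 336/577 scale), then compressed by the
  autoencoder to the latent width (256 by default);
* topology-based   -- [Phi(disease) || Phi(miRNA)] from the DeepWalk
  embedding, length 2n (256 at n = 128).

Pair ordering throughout is disease-major lexicographic for deterministic
batching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autoencoder import Autoencoder, AutoencoderSpec
from .deepwalk import EmbeddingMatrix
from .similarity import SimilarityMatrix

__all__ = [
    "PairFeatureVector",
    "similarity_pair_vector",
    "embedding_pair_vector",
    "train_autoencoder",
    "encode_pairs",
    "pair_matrix",
]


@dataclass
class PairFeatureVector:
    disease: str
    mirna: str
    values: np.ndarray
    source: str  # "similarity" or "deepwalk"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.source not in ("similarity", "deepwalk"):
            raise ValueError(f"unknown feature source {self.source!r}")


def similarity_pair_vector(
    disease: str, mirna: str, ds: SimilarityMatrix, rs: SimilarityMatrix
) -> PairFeatureVector:
    """Concatenate the disease's DS row with the miRNA's RS row."""
    values = np.concatenate([ds.row(disease), rs.row(mirna)])
    return PairFeatureVector(disease, mirna, values, "similarity")


def embedding_pair_vector(
    disease: str, mirna: str, phi: EmbeddingMatrix
) -> PairFeatureVector:
    """Concatenate the two nodes' embedding vectors (length 2n)."""
    values = np.concatenate([phi.vector(disease), phi.vector(mirna)])
    return PairFeatureVector(disease, mirna, values, "deepwalk")


def pair_matrix(vectors: list[PairFeatureVector]) -> np.ndarray:
    """Stack pair vectors into an (n_pairs, width) design matrix."""
    if not vectors:
        return np.empty((0, 0))
    return np.vstack([v.values for v in vectors])


def train_autoencoder(
    vectors: list[PairFeatureVector], spec: AutoencoderSpec
) -> Autoencoder:
    """Fit the compressing autoencoder on training pair vectors only."""
    if not vectors:
        raise ValueError("cannot train the autoencoder on an empty vector list")
    X = pair_matrix(vectors)
    if X.shape[1] != spec.input_dim:
        raise ValueError(
            f"pair vectors have width {X.shape[1]}, spec expects {spec.input_dim}"
        )
    return Autoencoder(spec).fit(X)


def encode_pairs(
    vectors: list[PairFeatureVector], encoder: Autoencoder
) -> list[PairFeatureVector]:
    """Apply the fitted encoder elementwise, preserving order and keys."""
    if not vectors:
        return []
    codes = encoder.encode(pair_matrix(vectors))
    return [
        PairFeatureVector(v.disease, v.mirna, codes[i], "similarity")
        for i, v in enumerate(vectors)
    ]
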