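"""Network embedding of the bipartite association network via random walks.

Truncated random walks over the (unweighted, undirected) disease-miRNA
association network are treated as sentences; node vectors are learned by
SkipGram, maximising the likelihood of the nodes seen within a window w
around each walk position.  The softmax over the vocabulary is factorised
through a Huffman-coded binary tree (hierarchical softmax): the probability
of a context node is the product, along its root-to-leaf path, of sigmoid
branch probabilities parameterised by internal-node vectors Psi and the
centre node's embedding Phi.

The stochastic-gradient inner loop is JIT-compiled with numba; the update
order is fixed, so training is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import heapq
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .similarity import AssociationNetwork

__all__ = [
    "WalkConfig",
    "EmbeddingMatrix",
    "HierarchicalSoftmaxTree",
    "generate_walks",
    "build_hs_tree",
    "leaf_probability",
    "corpus_loss",
    "train_skipgram",
]


@dataclass(frozen=True)
class WalkConfig:
    """Random-walk and SkipGram hyperparameters.

    ``walks_per_node`` (gamma) and ``walk_length`` (t) follow conventional
    DeepWalk settings; ``window`` and ``dim`` default to w=5 and n=128.
    The learning rate decays linearly to ``min_learning_rate`` over
    training.
    """

    walks_per_node: int = 10
    walk_length: int = 40
    window: int = 5
    dim: int = 128
    epochs: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1 or self.dim < 1:
            raise ValueError("window and dim must be >= 1")
        if self.walks_per_node < 1 or self.walk_length < 1 or self.epochs < 0:
            raise ValueError("walks_per_node, walk_length >= 1 and epochs >= 0")


@dataclass
class EmbeddingMatrix:
    """Per-node latent vectors Phi: one row per network node."""

    ids: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[0] != len(self.ids):
            raise ValueError("one vector row required per node ID")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding contains non-finite entries")
        self._index = {v: i for i, v in enumerate(self.ids)}

    def vector(self, node: str) -> np.ndarray:
        try:
            return self.vectors[self._index[node]]
        except KeyError:
            raise KeyError(f"node {node!r} has no embedding") from None

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def generate_walks(net: AssociationNetwork, cfg: WalkConfig) -> list[list[str]]:
    """gamma truncated random walks started from every network node.

    Each step moves to a uniformly random neighbour in the bipartite
    association network; a walk from an isolated node is just that node.
    """
    if not net.diseases and not net.mirnas:
        raise ValueError("association network has no nodes")
    adj: dict[str, list[str]] = {n: [] for n in net.diseases + net.mirnas}
    for d, m in sorted(net.edges):
        adj[d].append(m)
        adj[m].append(d)
    for nbrs in adj.values():
        nbrs.sort()

    rng = np.random.default_rng(cfg.seed)
    nodes = sorted(adj)
    walks: list[list[str]] = []
    for _ in range(cfg.walks_per_node):
        for start in nodes:
            walk = [start]
            cur = start
            while len(walk) < cfg.walk_length:
                nbrs = adj[cur]
                if not nbrs:
                    break
                cur = nbrs[rng.integers(len(nbrs))]
                walk.append(cur)
            walks.append(walk)
    return walks


@dataclass
class HierarchicalSoftmaxTree:
    """Huffman binary tree over corpus node frequencies.

    ``codes[v]`` holds the branch directions (0 left / 1 right) and
    ``points[v]`` the internal-node indices along the root-to-leaf path of
    node v.  ``psi`` is the (n_internal, dim) internal parameter matrix,
    initialised to zeros so every branch probability starts at 0.5.
    """

    leaves: list[str]
    codes: dict[str, np.ndarray]
    points: dict[str, np.ndarray]
    psi: np.ndarray
    frequencies: Counter = field(default_factory=Counter)

    @property
    def n_internal(self) -> int:
        return self.psi.shape[0]


def build_hs_tree(corpus: list[list[str]], dim: int) -> HierarchicalSoftmaxTree:
    """Huffman-code the corpus vocabulary; ties broken by node ID."""
    freq = Counter(node for walk in corpus for node in walk)
    if len(freq) < 1:
        raise ValueError("corpus covers no nodes")
    vocab = sorted(freq)

    # heap entries: (frequency, serial, payload); leaf serials follow
    # lexicographic ID order so equal-frequency ties are deterministic.
    heap: list[tuple[int, int, dict]] = []
    for serial, node in enumerate(vocab):
        heapq.heappush(heap, (freq[node], serial, {"leaf": node}))
    serial = len(vocab)
    n_internal = 0
    while len(heap) > 1:
        fa, _, a = heapq.heappop(heap)
        fb, _, b = heapq.heappop(heap)
        heapq.heappush(heap, (fa + fb, serial, {"id": n_internal, "l": a, "r": b}))
        serial += 1
        n_internal += 1

    codes: dict[str, np.ndarray] = {}
    points: dict[str, np.ndarray] = {}

    def descend(node: dict, code: list[int], path: list[int]) -> None:
        if "leaf" in node:
            codes[node["leaf"]] = np.array(code, dtype=np.int32)
            points[node["leaf"]] = np.array(path, dtype=np.int32)
            return
        descend(node["l"], code + [0], path + [node["id"]])
        descend(node["r"], code + [1], path + [node["id"]])

    root = heap[0][2]
    if "leaf" in root:  # single-node vocabulary: empty path, probability 1
        codes[root["leaf"]] = np.empty(0, dtype=np.int32)
        points[root["leaf"]] = np.empty(0, dtype=np.int32)
    else:
        descend(root, [], [])
    psi = np.zeros((max(n_internal, 1), dim))
    return HierarchicalSoftmaxTree(vocab, codes, points, psi, freq)


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def leaf_probability(
    v: str, context: str, tree: HierarchicalSoftmaxTree, phi: EmbeddingMatrix
) -> float:
    """P(v | context) under the hierarchical softmax.

    Product over v's path of sigmoid(+/- Phi(context) . Psi(b)), the sign
    set by the branch direction; sums to 1 over all leaves by construction.
    """
    vec = phi.vector(context)
    code, path = tree.codes[v], tree.points[v]
    p = 1.0
    for d, b in zip(code, path):
        x = float(vec @ tree.psi[b])
        p *= _sigmoid(-x) if d else _sigmoid(x)
    return p


def corpus_loss(
    corpus: list[list[str]],
    tree: HierarchicalSoftmaxTree,
    phi: EmbeddingMatrix,
    window: int,
) -> float:
    """Mean negative log-likelihood of in-window co-occurrences."""
    total, count = 0.0, 0
    for walk in corpus:
        for i, center in enumerate(walk):
            lo, hi = max(0, i - window), min(len(walk), i + window + 1)
            for j in range(lo, hi):
                if j == i:
                    continue
                p = leaf_probability(walk[j], center, tree, phi)
                total -= np.log(max(p, 1e-300))
                count += 1
    return total / max(count, 1)


@njit(cache=True)
def _sgd_epochs(  # pragma: no cover - exercised through train_skipgram
    walks: np.ndarray,
    walk_lens: np.ndarray,
    codes: np.ndarray,
    points: np.ndarray,
    path_lens: np.ndarray,
    phi: np.ndarray,
    psi: np.ndarray,
    window: int,
    epochs: int,
    lr0: float,
    lr_min: float,
) -> None:
    n_walks = walks.shape[0]
    total_centers = 0
    for w in range(n_walks):
        total_centers += walk_lens[w]
    total_centers *= max(epochs, 1)
    processed = 0
    dim = phi.shape[1]
    err = np.empty(dim)
    for _ in range(epochs):
        for w in range(n_walks):
            ln = walk_lens[w]
            for i in range(ln):
                lr = lr0 * (1.0 - processed / total_centers)
                if lr < lr_min:
                    lr = lr_min
                processed += 1
                center = walks[w, i]
                lo = i - window
                if lo < 0:
                    lo = 0
                hi = i + window + 1
                if hi > ln:
                    hi = ln
                for j in range(lo, hi):
                    if j == i:
                        continue
                    ctx = walks[w, j]
                    for k in range(dim):
                        err[k] = 0.0
                    for step in range(path_lens[ctx]):
                        b = points[ctx, step]
                        d = codes[ctx, step]
                        x = 0.0
                        for k in range(dim):
                            x += phi[center, k] * psi[b, k]
                        f = 1.0 / (1.0 + np.exp(-x))
                        g = lr * ((1.0 - d) - f)
                        for k in range(dim):
                            err[k] += g * psi[b, k]
                            psi[b, k] += g * phi[center, k]
                    for k in range(dim):
                        phi[center, k] += err[k]


def train_skipgram(
    corpus: list[list[str]],
    cfg: WalkConfig,
    tree: HierarchicalSoftmaxTree | None = None,
    return_losses: bool = False,
) -> EmbeddingMatrix | tuple[EmbeddingMatrix, list[float]]:
    """Learn node embeddings from a walk corpus by hierarchical-softmax SGD.

    Phi is initialised uniformly in [-0.5/n, 0.5/n] (seeded) and updated by
    ascending the in-window co-occurrence log-likelihood; Psi starts at
    zero.  With ``return_losses`` the corpus mean negative log-likelihood
    is recorded before training and after every epoch.
    """
    if cfg.dim <= 0:
        raise ValueError("embedding dimension must be positive")
    if not corpus:
        raise ValueError("walk corpus is empty")
    if tree is None:
        tree = build_hs_tree(corpus, cfg.dim)
    vocab = tree.leaves
    index = {v: i for i, v in enumerate(vocab)}

    rng = np.random.default_rng(cfg.seed)
    phi = rng.uniform(-0.5 / cfg.dim, 0.5 / cfg.dim, size=(len(vocab), cfg.dim))

    max_len = max(len(w) for w in corpus)
    walks = np.zeros((len(corpus), max_len), dtype=np.int32)
    walk_lens = np.zeros(len(corpus), dtype=np.int32)
    for i, walk in enumerate(corpus):
        walk_lens[i] = len(walk)
        for j, node in enumerate(walk):
            walks[i, j] = index[node]
    max_path = max((len(tree.codes[v]) for v in vocab), default=0)
    codes = np.zeros((len(vocab), max(max_path, 1)), dtype=np.int32)
    points = np.zeros((len(vocab), max(max_path, 1)), dtype=np.int32)
    path_lens = np.zeros(len(vocab), dtype=np.int32)
    for v, i in index.items():
        c, p = tree.codes[v], tree.points[v]
        path_lens[i] = len(c)
        codes[i, : len(c)] = c
        points[i, : len(c)] = p

    losses: list[float] = []
    if return_losses:
        losses.append(corpus_loss(corpus, tree, EmbeddingMatrix(vocab, phi), cfg.window))
    if cfg.epochs and return_losses:
        for _ in range(cfg.epochs):
            _sgd_epochs(
                walks, walk_lens, codes, points, path_lens, phi, tree.psi,
                cfg.window, 1, cfg.learning_rate, cfg.min_learning_rate,
            )
            losses.append(
                corpus_loss(corpus, tree, EmbeddingMatrix(vocab, phi), cfg.window)
            )
    elif cfg.epochs:
        _sgd_epochs(
            walks, walk_lens, codes, points, path_lens, phi, tree.psi,
            cfg.window, cfg.epochs, cfg.learning_rate, cfg.min_learning_rate,
        )
    emb = EmbeddingMatrix(vocab, phi)
    return (emb, losses) if return_losses else emb
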