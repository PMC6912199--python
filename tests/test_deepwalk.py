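"""Random-walk, hierarchical-softmax and SkipGram training tests."""

import numpy as np
import pytest
from scipy import stats

from miralink.deepwalk import (
    EmbeddingMatrix,
    WalkConfig,
    build_hs_tree,
    corpus_loss,
    generate_walks,
    leaf_probability,
    train_skipgram,
)
from miralink.similarity import AssociationNetwork


def _path_graph(n_d=3, n_m=2):
    """Small fully-connected bipartite network for walk tests."""
    diseases = [f"d{i}" for i in range(n_d)]
    mirnas = [f"m{i}" for i in range(n_m)]
    edges = {(d, m) for d in diseases for m in mirnas}
    return AssociationNetwork(diseases, mirnas, edges)


class TestWalks:
    def test_walk_count_and_length(self):
        net = _path_graph(3, 2)  # 5 nodes, all connected
        walks = generate_walks(net, WalkConfig(walks_per_node=2, walk_length=4, seed=0))
        assert len(walks) == 10
        assert all(len(w) == 4 for w in walks)

    def test_isolated_node_walk_is_singleton(self):
        net = AssociationNetwork(["d0", "d1"], ["m0"], {("d0", "m0")})
        walks = generate_walks(net, WalkConfig(walks_per_node=1, walk_length=5, seed=0))
        iso = [w for w in walks if w[0] == "d1"]
        assert iso == [["d1"]]

    def test_steps_follow_network_edges(self):
        net = _path_graph(4, 3)
        edges = {frozenset(e) for e in net.edges}
        walks = generate_walks(net, WalkConfig(walks_per_node=3, walk_length=10, seed=1))
        nodes = set(net.diseases + net.mirnas)
        for walk in walks:
            assert set(walk) <= nodes
            for a, b in zip(walk, walk[1:]):
                assert frozenset((a, b)) in edges

    def test_star_graph_next_hop_is_uniform(self):
        # star: one disease linked to three miRNAs; next hops from the
        # center should be uniform over the three leaves (chi^2 p > 0.01)
        net = AssociationNetwork(["c"], ["x", "y", "z"], {("c", "x"), ("c", "y"), ("c", "z")})
        walks = generate_walks(net, WalkConfig(walks_per_node=150, walk_length=40, seed=2))
        counts = {"x": 0, "y": 0, "z": 0}
        total = 0
        for walk in walks:
            for a, b in zip(walk, walk[1:]):
                if a == "c":
                    counts[b] += 1
                    total += 1
        assert total > 10_000
        _, p = stats.chisquare(list(counts.values()))
        assert p > 0.01

    def test_identical_seed_identical_corpus(self):
        net = _path_graph(4, 4)
        cfg = WalkConfig(seed=7)
        assert generate_walks(net, cfg) == generate_walks(net, cfg)


class TestHierarchicalSoftmax:
    def test_two_leaves_share_the_root(self):
        tree = build_hs_tree([["a", "b", "a"]], dim=4)
        assert len(tree.points["a"]) == 1 and len(tree.points["b"]) == 1
        assert tree.points["a"][0] == tree.points["b"][0]

    def test_four_equal_frequency_leaves_have_depth_two(self):
        corpus = [["a", "b", "c", "d"]]
        tree = build_hs_tree(corpus, dim=4)
        assert all(len(tree.codes[v]) == 2 for v in "abcd")

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_hs_tree([], dim=4)

    def test_zero_parameters_give_half_per_branch(self, rng):
        corpus = [list("abcdefgh")]
        tree = build_hs_tree(corpus, dim=4)
        phi = EmbeddingMatrix(tree.leaves, rng.normal(size=(8, 4)))
        for v in "abcdefgh":
            depth = len(tree.codes[v])
            assert leaf_probability(v, "a", tree, phi) == pytest.approx(0.5**depth)

    def test_two_leaf_probabilities_sum_to_one(self, rng):
        tree = build_hs_tree([["a", "b"]], dim=3)
        tree.psi[:] = rng.normal(size=tree.psi.shape)
        phi = EmbeddingMatrix(tree.leaves, rng.normal(size=(2, 3)))
        p = leaf_probability("a", "b", tree, phi) + leaf_probability("b", "b", tree, phi)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("n_leaves", [2, 5, 17, 32])
    def test_leaf_probabilities_normalize_for_random_parameters(self, n_leaves, rng):
        nodes = [f"v{i:02d}" for i in range(n_leaves)]
        corpus = [list(rng.choice(nodes, size=200))]
        tree = build_hs_tree(corpus, dim=6)
        tree.psi[:] = rng.normal(size=tree.psi.shape)
        phi = EmbeddingMatrix(tree.leaves, rng.normal(size=(len(tree.leaves), 6)))
        for ctx in tree.leaves[:3]:
            total = sum(leaf_probability(v, ctx, tree, phi) for v in tree.leaves)
            assert total == pytest.approx(1.0, abs=1e-9)


class TestSkipGram:
    def test_output_shape_matches_vocabulary_and_dim(self):
        net = _path_graph(3, 3)
        cfg = WalkConfig(walks_per_node=2, walk_length=8, dim=16, epochs=1, seed=0)
        phi = train_skipgram(generate_walks(net, cfg), cfg)
        assert phi.vectors.shape == (6, 16)

    def test_zero_epochs_keep_initialization(self):
        corpus = [["a", "b", "a", "b"]]
        cfg = WalkConfig(dim=8, epochs=0, seed=3)
        phi = train_skipgram(corpus, cfg)
        rng = np.random.default_rng(3)
        expected = rng.uniform(-0.5 / 8, 0.5 / 8, size=(2, 8))
        np.testing.assert_array_equal(phi.vectors, expected)

    def test_identical_seed_identical_embedding(self):
        net = _path_graph(3, 3)
        cfg = WalkConfig(walks_per_node=2, walk_length=10, dim=8, epochs=2, seed=5)
        a = train_skipgram(generate_walks(net, cfg), cfg)
        b = train_skipgram(generate_walks(net, cfg), cfg)
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_loss_non_increasing_over_epochs(self):
        net = _path_graph(4, 4)
        cfg = WalkConfig(walks_per_node=3, walk_length=12, dim=8, epochs=5, seed=2)
        _, losses = train_skipgram(generate_walks(net, cfg), cfg, return_losses=True)
        assert losses[-1] < losses[0]
        for prev, cur in zip(losses, losses[1:]):
            assert cur <= prev * 1.05  # SGD wobble tolerance

    def test_disjoint_blocks_embed_closer_within_than_across(self):
        # two disjoint complete bipartite blocks; embeddings should place
        # same-block nodes closer (higher cosine) than cross-block nodes
        d = [f"d{i}" for i in range(4)]
        m = [f"m{i}" for i in range(4)]
        edges = {(d[i], m[j]) for i in range(2) for j in range(2)}
        edges |= {(d[i], m[j]) for i in range(2, 4) for j in range(2, 4)}
        net = AssociationNetwork(d, m, edges)
        cfg = WalkConfig(walks_per_node=20, walk_length=20, window=3, dim=16, epochs=5, seed=4)
        phi = train_skipgram(generate_walks(net, cfg), cfg)
        block = {n: (0 if n in {"d0", "d1", "m0", "m1"} else 1) for n in d + m}
        unit = {n: phi.vector(n) / np.linalg.norm(phi.vector(n)) for n in d + m}
        within, across = [], []
        nodes = d + m
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                cos = float(unit[a] @ unit[b])
                (within if block[a] == block[b] else across).append(cos)
        assert np.mean(within) > np.mean(across)

    def test_negative_dim_rejected(self):
        with pytest.raises(ValueError):
            WalkConfig(dim=0)


def test_corpus_loss_matches_leaf_probability_sum():
    corpus = [["a", "b", "c", "a"]]
    cfg = WalkConfig(dim=4, epochs=0, window=1, seed=0)
    phi = train_skipgram(corpus, cfg)
    tree = build_hs_tree(corpus, 4)
    loss = corpus_loss(corpus, tree, phi, window=1)
    # manual: every in-window pair contributes -log p
    total, count = 0.0, 0
    for walk in corpus:
        for i, center in enumerate(walk):
            for j in range(max(0, i - 1), min(len(walk), i + 2)):
                if j != i:
                    total -= np.log(leaf_probability(walk[j], center, tree, phi))
                    count += 1
    assert loss == pytest.approx(total / count)
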