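"""Similarity-layer unit tests: LLS aggregation, DS, RST/RSF/RSC and RS."""

import numpy as np
import pytest

from miralink.similarity import (
    GeneNetwork,
    SimilarityMatrix,
    SimilarityWeights,
    combine_rs_matrix,
    compute_ds_matrix,
    compute_rst_matrix,
    lls_gene_to_set,
    membership_similarity,
)


@pytest.fixture()
def toy_net():
    return GeneNetwork([("g", "x", 1.5), ("g", "y", 2.5), ("g", "z", 9.0)])


class TestLLSAggregation:
    def test_sum_over_edges_into_set(self, toy_net):
        assert lls_gene_to_set("g", {"x", "y"}, toy_net) == pytest.approx(4.0)

    def test_no_edges_into_set_is_zero(self, toy_net):
        assert lls_gene_to_set("g", {"unrelated"}, toy_net) == 0.0
        assert lls_gene_to_set("absent", {"x"}, toy_net) == 0.0

    def test_empty_set_is_zero(self, toy_net):
        assert lls_gene_to_set("g", set(), toy_net) == 0.0

    def test_max_aggregation_alternative(self, toy_net):
        assert lls_gene_to_set("g", {"x", "y"}, toy_net, "max") == pytest.approx(2.5)


def _naive_ds(disease_genes, net, diseases):
    """Independent double-loop oracle for the disease-similarity formula."""
    m = len(diseases)
    out = np.zeros((m, m))
    for i, di in enumerate(diseases):
        for j, dj in enumerate(diseases):
            si, sj = disease_genes[di], disease_genes[dj]
            if len(si) + len(sj) == 0:
                continue
            total = 0.0
            for g1 in si:
                total += sum(net.weight(g1, g) for g in sj)
            for g2 in sj:
                total += sum(net.weight(g2, g) for g in si)
            out[i, j] = total / (len(si) + len(sj))
    return out


class TestDiseaseSimilarity:
    def test_both_sets_empty_gives_zero(self):
        ds = compute_ds_matrix({"d1": set(), "d2": set()}, GeneNetwork(), ["d1", "d2"])
        assert np.all(ds.values == 0.0)

    def test_hand_evaluated_single_edge(self):
        net = GeneNetwork([("g1", "g2", 2.0)])
        ds = compute_ds_matrix({"d1": {"g1"}, "d2": {"g2"}}, net, ["d1", "d2"])
        assert ds["d1", "d2"] == pytest.approx(2.0)

    def test_unknown_disease_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            compute_ds_matrix({"d1": set()}, GeneNetwork(), ["d1", "ghost"])

    def test_matches_naive_oracle_on_random_network(self, rng):
        genes = [f"g{i}" for i in range(30)]
        net = GeneNetwork()
        for _ in range(120):
            a, b = rng.choice(30, size=2, replace=False)
            net.add_edge(genes[a], genes[b], float(rng.uniform(0.1, 3.0)))
        diseases = [f"d{i}" for i in range(15)]
        dmap = {
            d: {genes[k] for k in rng.choice(30, size=rng.integers(0, 8), replace=False)}
            for d in diseases
        }
        ds = compute_ds_matrix(dmap, net, diseases)
        np.testing.assert_allclose(ds.values, _naive_ds(dmap, net, diseases), atol=1e-12)
        assert np.max(np.abs(ds.values - ds.values.T)) < 1e-9

    def test_lls_scaling_scales_ds_linearly(self, rng):
        genes = [f"g{i}" for i in range(10)]
        edges = [
            (genes[i], genes[j], float(rng.uniform(0.5, 2)))
            for i in range(10)
            for j in range(i + 1, 10)
            if rng.random() < 0.4
        ]
        dmap = {"a": {"g0", "g1"}, "b": {"g2", "g3", "g4"}, "c": set()}
        ds1 = compute_ds_matrix(dmap, GeneNetwork(edges), ["a", "b", "c"])
        scaled = [(x, y, 3.0 * w) for x, y, w in edges]
        ds3 = compute_ds_matrix(dmap, GeneNetwork(scaled), ["a", "b", "c"])
        np.testing.assert_allclose(ds3.values, 3.0 * ds1.values, rtol=1e-12)


class TestMirnaSimilarity:
    def test_shared_target_count_raw(self):
        targets = {"r1": {"t1", "t2", "t3", "t4"}, "r2": {"t2", "t3", "t4"}}
        rst = compute_rst_matrix(targets, ["r1", "r2"], normalize=False)
        assert rst["r1", "r2"] == 3.0
        assert rst["r1", "r1"] == 0.0  # diagonal forced to zero

    def test_disjoint_targets_zero_and_missing_mirna_empty(self):
        rst = compute_rst_matrix({"r1": {"t1"}, "r2": {"t2"}}, ["r1", "r2", "r3"])
        assert np.all(rst.values == 0.0) or rst["r1", "r2"] == 0.0
        assert rst["r1", "r3"] == 0.0

    def test_normalized_entries_in_unit_interval(self):
        targets = {"r1": {"t1", "t2"}, "r2": {"t1", "t2"}, "r3": {"t1"}}
        rst = compute_rst_matrix(targets, ["r1", "r2", "r3"], normalize=True)
        assert rst.values.max() == pytest.approx(1.0)
        assert rst.values.min() >= 0.0

    def test_all_zero_counts_no_division_by_zero(self):
        rst = compute_rst_matrix({}, ["r1", "r2"], normalize=True)
        assert np.all(rst.values == 0.0)

    def test_membership_matrix_enumerated(self):
        groups = {"r1": {"f1"}, "r2": {"f1"}, "r3": {"f2"}}
        mat = membership_similarity(groups, ["r1", "r2", "r3"])
        np.testing.assert_array_equal(
            mat.values, [[1, 1, 0], [1, 1, 0], [0, 0, 1]]
        )

    def test_unannotated_mirna_matches_nothing(self):
        mat = membership_similarity({"r1": {"f1"}}, ["r1", "r2"])
        assert mat["r1", "r2"] == 0.0
        assert mat["r2", "r2"] == 0.0  # no group: diagonal 0


class TestCombination:
    def _mats(self, ids, *arrays):
        return [SimilarityMatrix(ids, np.array(a, dtype=float)) for a in arrays]

    def test_hand_evaluated_default_weights(self):
        ids = ["r1", "r2"]
        off = lambda v: [[0.0, v], [v, 0.0]]
        rst, rsf, rsc, rsd = self._mats(ids, off(1.0), off(1.0), off(0.0), off(0.4))
        rs = combine_rs_matrix(rst, rsf, rsc, rsd)
        assert rs["r1", "r2"] == pytest.approx(0.2 + 0.1 + 0.0 + 0.2)

    def test_all_zero_inputs_give_zero(self):
        ids = ["a", "b"]
        z = [[0.0, 0.0], [0.0, 0.0]]
        rs = combine_rs_matrix(*self._mats(ids, z, z, z, z))
        assert np.all(rs.values == 0.0)

    def test_unit_alpha_returns_rst_exactly(self, rng):
        ids = ["a", "b", "c"]
        sym = rng.random((3, 3))
        sym = (sym + sym.T) / 2
        mats = self._mats(ids, sym, rng.random((3, 3)) * 0, sym * 0.5, sym * 0.1)
        rs = combine_rs_matrix(*mats, SimilarityWeights(1.0, 0.0, 0.0, 0.0))
        np.testing.assert_array_equal(rs.values, mats[0].values)

    def test_mismatched_ids_rejected(self):
        a = SimilarityMatrix(["x"], np.zeros((1, 1)))
        b = SimilarityMatrix(["y"], np.zeros((1, 1)))
        with pytest.raises(ValueError, match="mismatched"):
            combine_rs_matrix(a, a, a, b)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            SimilarityWeights(alpha=-0.1)
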