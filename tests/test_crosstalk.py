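"""Crosstalk-network construction against independent brute-force oracles.

The expected values for the worked 3-cell/2-GO fixture were computed by
hand with plain set arithmetic and statistics.median:
  J(A,GO1) = |{g1,g2}| / |{g1,g2,g3}| = 2/3, med(2,4) = 3, W = 2.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from citmic import (
    GeneSet,
    GeneSetCollection,
    bipartite_weights,
    crosstalk_adjacency,
    jaccard_matrix,
    median_overlap_expression,
)
from citmic.crosstalk import OverlapIndex, crosstalk_edge_list

from conftest import bipartite_bf, crosstalk_bf, jaccard_bf


class TestJaccard:
    def test_worked_values(self, toy):
        cells, gos, _ = toy
        J = jaccard_matrix(cells, gos)
        assert J.loc["A", "GO1"] == pytest.approx(2 / 3, abs=1e-12)
        assert J.loc["B", "GO1"] == 1.0          # identical sets
        assert J.loc["C", "GO1"] == 0.0          # disjoint
        assert J.loc["C", "GO2"] == pytest.approx(2 / 3, abs=1e-12)

    def test_range_and_empty_pair(self):
        cells = GeneSetCollection([GeneSet("empty", set()),
                                   GeneSet("full", {"g1"})])
        gos = GeneSetCollection([GeneSet("e2", set())], kind="go_bp")
        J = jaccard_matrix(cells, gos)
        assert J.loc["empty", "e2"] == 0.0   # both empty -> defined as 0
        assert J.loc["full", "e2"] == 0.0

    @given(data=st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_bruteforce_on_random_sets(self, data):
        universe = [f"g{i}" for i in range(12)]
        cells = GeneSetCollection([
            GeneSet(f"c{k}", set(data.draw(
                st.lists(st.sampled_from(universe), min_size=1, max_size=8))))
            for k in range(3)])
        gos = GeneSetCollection([
            GeneSet(f"t{k}", set(data.draw(
                st.lists(st.sampled_from(universe), min_size=1, max_size=8))),
                "go_bp")
            for k in range(3)], kind="go_bp")
        J = jaccard_matrix(cells, gos).to_numpy()
        expected = np.array([[jaccard_bf(set(c.genes), set(g.genes))
                              for g in gos] for c in cells])
        np.testing.assert_allclose(J, expected, atol=1e-12)
        assert ((J >= 0) & (J <= 1)).all()


class TestMedianOverlap:
    def test_worked_values(self, toy):
        cells, gos, expr = toy
        M = median_overlap_expression(cells, gos, expr)
        assert M.loc["A", "GO1"] == 3.0    # median(2, 4): midpoint average
        assert M.loc["C", "GO2"] == 4.0    # median(5, 3)
        assert M.loc["C", "GO1"] == 0.0    # empty overlap
        assert M.loc["B", "GO2"] == 0.0

    def test_singleton_median(self):
        cells = GeneSetCollection([GeneSet("c", {"g5", "g9"})])
        gos = GeneSetCollection([GeneSet("t", {"g5"}, "go_bp")], kind="go_bp")
        expr = pd.Series({"g5": 5.0, "g9": 1.0})
        assert median_overlap_expression(cells, gos, expr).iloc[0, 0] == 5.0

    def test_missing_gene_is_contract_violation(self, toy):
        cells, gos, expr = toy
        with pytest.raises(ValueError, match="restrict"):
            median_overlap_expression(cells, gos, expr.drop("g1"))


class TestBipartiteWeights:
    def test_product_of_worked_examples(self, toy):
        cells, gos, expr = toy
        J = jaccard_matrix(cells, gos)
        M = median_overlap_expression(cells, gos, expr)
        W = bipartite_weights(J, M)
        assert W.loc["A", "GO1"] == pytest.approx(2.0, abs=1e-12)  # 2/3 * 3
        assert (W.to_numpy()[(J.to_numpy() == 0) | (M.to_numpy() == 0)] == 0).all()

    def test_all_ones_jaccard_is_identity_on_medians(self, toy):
        cells, gos, expr = toy
        M = median_overlap_expression(cells, gos, expr)
        ones = pd.DataFrame(1.0, index=M.index, columns=M.columns)
        pd.testing.assert_frame_equal(bipartite_weights(ones, M), M)

    def test_shape_mismatch(self, toy):
        cells, gos, expr = toy
        J = jaccard_matrix(cells, gos)
        with pytest.raises(ValueError):
            bipartite_weights(J, J.iloc[:, :1])


class TestCrosstalkAdjacency:
    def test_single_shared_go_term_product(self):
        W = pd.DataFrame([[2.0], [3.0]], index=["c1", "c2"])
        R = crosstalk_adjacency(W)
        assert R.loc["c1", "c2"] == 6.0
        assert R.loc["c1", "c1"] == 0.0

    def test_disjoint_go_neighborhoods_give_zero(self):
        W = pd.DataFrame([[1.0, 0.0], [0.0, 2.0]], index=["c1", "c2"])
        assert crosstalk_adjacency(W).loc["c1", "c2"] == 0.0

    def test_single_cell_is_zero_matrix(self):
        W = pd.DataFrame([[5.0, 1.0]], index=["c1"])
        assert (crosstalk_adjacency(W).to_numpy() == 0).all()

    def test_matches_triple_loop_on_toy(self, toy):
        cells, gos, expr = toy
        Wbf = bipartite_bf(list(cells), list(gos), expr.to_dict())
        J = jaccard_matrix(cells, gos)
        M = median_overlap_expression(cells, gos, expr)
        W = bipartite_weights(J, M)
        np.testing.assert_allclose(W.to_numpy(), Wbf, atol=1e-12)
        R = crosstalk_adjacency(W).to_numpy()
        np.testing.assert_allclose(R, crosstalk_bf(Wbf), rtol=1e-9, atol=1e-12)
        assert (R == R.T).all()
        assert (np.diag(R) == 0).all()

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_triple_loop_on_random_weights(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.uniform(size=(4, 6)) * (rng.uniform(size=(4, 6)) < 0.6)
        R = crosstalk_adjacency(pd.DataFrame(W)).to_numpy()
        np.testing.assert_allclose(R, crosstalk_bf(W), rtol=1e-9, atol=1e-12)


class TestCohortInvariants:
    def test_expression_scaling_scales_M_by_alpha_R_by_alpha_sq(self, toy):
        cells, gos, expr = toy
        alpha = 3.5
        M1 = median_overlap_expression(cells, gos, expr)
        M2 = median_overlap_expression(cells, gos, alpha * expr)
        pd.testing.assert_frame_equal(M2, alpha * M1)
        J = jaccard_matrix(cells, gos)
        R1 = crosstalk_adjacency(bipartite_weights(J, M1)).to_numpy()
        R2 = crosstalk_adjacency(bipartite_weights(J, M2)).to_numpy()
        np.testing.assert_allclose(R2, alpha ** 2 * R1, rtol=1e-12)

    def test_cell_permutation_equivariance(self, toy):
        cells, gos, expr = toy
        perm = ["C", "A", "B"]
        cells_p = GeneSetCollection([cells[n] for n in perm])
        J = jaccard_matrix(cells, gos)
        M = median_overlap_expression(cells, gos, expr)
        R = crosstalk_adjacency(bipartite_weights(J, M))
        Jp = jaccard_matrix(cells_p, gos)
        Mp = median_overlap_expression(cells_p, gos, expr)
        Rp = crosstalk_adjacency(bipartite_weights(Jp, Mp))
        pd.testing.assert_frame_equal(Rp, R.loc[perm, perm])

    def test_jaccard_is_sample_independent(self, toy_cohort):
        co = toy_cohort
        from citmic import restrict_to_universe
        cells = restrict_to_universe(co.cell_sets, co.expression.index,
                                     drop_empty=False)
        gos = restrict_to_universe(co.go_sets, co.expression.index)
        J_once = jaccard_matrix(cells, gos)
        for _ in co.expression.columns:
            pd.testing.assert_frame_equal(jaccard_matrix(cells, gos), J_once)

    def test_overlap_index_matches_direct_medians(self, toy_cohort):
        co = toy_cohort
        idx = OverlapIndex.build(co.cell_sets, co.go_sets,
                                 list(co.expression.index))
        for sample in co.expression.columns:
            M_fast = idx.median_matrix(co.expression[sample].to_numpy())
            M_ref = median_overlap_expression(co.cell_sets, co.go_sets,
                                              co.expression[sample])
            np.testing.assert_allclose(M_fast, M_ref.to_numpy(), atol=1e-12)


def test_edge_list_upper_triangle(toy):
    cells, gos, expr = toy
    from citmic import compute_inscore_sample  # noqa: F401  (import check)
    J = jaccard_matrix(cells, gos)
    M = median_overlap_expression(cells, gos, expr)
    R = crosstalk_adjacency(bipartite_weights(J, M))
    edges = crosstalk_edge_list(R)
    assert set(edges.columns) == {"cell_i", "cell_j", "weight"}
    for _, row in edges.iterrows():
        assert row.weight == R.loc[row.cell_i, row.cell_j]
    assert (edges.weight != 0).all()
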