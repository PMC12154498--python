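"""Genetic distances and neighbor joining: hand values, additivity, oracles."""

import numpy as np
import pytest

from kaspanel.distance import (DistanceError, DistanceMatrix, ce_distance,
                               ce_matrix, mrd_distance, mrd_matrix,
                               nei_da_distance, neighbor_joining,
                               path_length_matrix)
from conftest import make_matrix


class TestNeiDA:
    def test_identical_homozygotes_zero(self):
        mat = make_matrix([["AA", "GG"], ["AA", "GG"]])
        assert nei_da_distance(mat).d[0, 1] == pytest.approx(0.0)

    def test_opposite_fixed_is_one(self):
        mat = make_matrix([["AA", "AA"], ["GG", "GG"]])
        assert nei_da_distance(mat).d[0, 1] == pytest.approx(1.0)

    def test_hand_value_hom_vs_het(self):
        # one locus, AA vs AG: DA = 1 - sqrt(1*0.5) = 0.29289
        mat = make_matrix([["AA"], ["AG"]])
        assert nei_da_distance(mat).d[0, 1] == pytest.approx(1 - np.sqrt(0.5),
                                                             abs=1e-6)

    def test_pairwise_deletion_and_no_shared_loci_error(self):
        mat = make_matrix([["AA", "NN"], ["NN", "GG"]])
        with pytest.raises(DistanceError, match="share no"):
            nei_da_distance(mat)

    def test_locus_order_invariance(self):
        mat = make_matrix([["AA", "AG", "GG"], ["AG", "GG", "AA"]])
        rev = mat.subset(markers=[2, 1, 0])
        assert nei_da_distance(mat).d[0, 1] == pytest.approx(
            nei_da_distance(rev).d[0, 1])

    def test_within_less_than_between_for_diverged_pops(self, structured_panel):
        gm = structured_panel.genotypes
        pop = np.argmax(structured_panel.true_Q, axis=1)
        d = nei_da_distance(gm).d
        same = pop[:, None] == pop[None, :]
        triu = np.triu(np.ones_like(d, dtype=bool), 1)
        assert d[same & triu].mean() < d[~same & triu].mean()


class TestRogersAndCE:
    def test_identical_zero(self):
        assert mrd_distance([1.0, 0.0], [1.0, 0.0]) == 0.0
        assert ce_distance([1.0, 0.0], [1.0, 0.0]) == 0.0

    def test_opposite_fixed_is_one(self):
        # per locus sum of squared freq differences = 2; sqrt(2L/(2L)) = 1
        x, y = [1.0, 1.0, 1.0], [0.0, 0.0, 0.0]
        assert mrd_distance(x, y) == pytest.approx(1.0)
        assert ce_distance(x, y) == pytest.approx(1.0)

    def test_matrices_symmetric_zero_diagonal(self, small_panel):
        for fn in (mrd_matrix, ce_matrix, nei_da_distance):
            dm = fn(small_panel.genotypes.subset(samples=range(10)))
            assert np.allclose(dm.d, dm.d.T)
            assert np.allclose(np.diag(dm.d), 0)
            assert (dm.d >= 0).all() and (dm.d <= 1 + 1e-9).all()


def _additive_matrix():
    """Distances from the tree ((A:1,B:2):1,(C:1,D:1))."""
    ids = ["A", "B", "C", "D"]
    d = np.array([
        [0, 3, 3, 3],
        [3, 0, 4, 4],
        [3, 4, 0, 2],
        [3, 4, 2, 0],
    ], dtype=float)
    return DistanceMatrix(ids, d)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    def test_additive_four_taxon_recovery(self):
        dm = _additive_matrix()
        tree = neighbor_joining(dm)
        assert np.allclose(path_length_matrix(tree, dm.ids), dm.d, atol=1e-9)
        # topology: A,B on one side of the internal edge
        ab = tree.lowest_common_ancestor(["A", "B"])
        assert {t.name for t in ab.tips()} == {"A", "B"}

    def test_random_additive_matrices_recovered(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            # random caterpillar tree -> additive distances via path lengths
            n = 7
            ids = [f"T{i}" for i in range(n)]
            from skbio import TreeNode
            tips = [TreeNode(name=i, length=float(rng.uniform(0.1, 2)))
                    for i in ids]
            root = TreeNode(children=[tips[0], tips[1]])
            for t in tips[2:]:
                root = TreeNode(children=[root, t])
                root.children[0].length = float(rng.uniform(0.1, 2))
            root.children[1].length = 0.0
            d = np.zeros((n, n))
            lookup = {t.name: t for t in root.tips()}
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = lookup[ids[i]].distance(lookup[ids[j]])
            dm = DistanceMatrix(ids, d)
            tree = neighbor_joining(dm)
            assert np.allclose(path_length_matrix(tree, ids), d, atol=1e-9)

    def test_agrees_with_skbio_reference(self):
        # independent implementation check on an additive matrix
        import skbio
        dm = _additive_matrix()
        ref = skbio.tree.nj(skbio.DistanceMatrix(dm.d, dm.ids))
        ours = neighbor_joining(dm)
        ref_paths = np.array([[ref.find(a).distance(ref.find(b))
                               for b in dm.ids] for a in dm.ids])
        assert np.allclose(path_length_matrix(ours, dm.ids), ref_paths, atol=1e-9)

    def test_equal_distance_tie_case_path_lengths(self):
        dm = DistanceMatrix(list("ABCD"), np.ones((4, 4)) - np.eye(4))
        tree = neighbor_joining(dm)
        paths = path_length_matrix(tree, dm.ids)
        assert np.allclose(paths[~np.eye(4, dtype=bool)], 1.0, atol=1e-9)

    def test_too_few_taxa_rejected(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(DistanceError):
            neighbor_joining(dm)

    def test_negative_branch_clamped_nonnegative(self):
        d = np.array([[0, 1, 1, 1],
                      [1, 0, 1.9, 1.9],
                      [1, 1.9, 0, 0.1],
                      [1, 1.9, 0.1, 0]])
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0
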