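"""Partition metric properties and classical-scaling closed forms."""

import dendropy
import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import phyloconverge as pc

from conftest import random_tree


class TestRFDistance:
    def test_identity(self):
        t = random_tree(10, 1)
        assert pc.rf_distance(t, pc.parse_newick(pc.write_newick(t))) == 0

    def test_split_disjoint_five_tip_trees(self):
        t1 = pc.parse_newick("((A,B),(C,D),E);")
        t2 = pc.parse_newick("((A,C),(B,D),E);")
        assert pc.rf_distance(t1, t2) == 4

    def test_mismatched_tip_sets_listed(self):
        t1 = pc.parse_newick("((A,B),(C,D));")
        t2 = pc.parse_newick("((A,B),(C,E));")
        with pytest.raises(ValueError, match="E"):
            pc.rf_distance(t1, t2)

    @pytest.mark.parametrize("seed", range(30))
    def test_metric_axioms(self, seed):
        a, b, c = (random_tree(9, seed * 3 + k) for k in range(3))
        dab, dba = pc.rf_distance(a, b), pc.rf_distance(b, a)
        assert dab == dba >= 0
        assert pc.rf_distance(a, a) == 0
        assert pc.rf_distance(a, c) <= dab + pc.rf_distance(b, c)
        assert dab <= 2 * (9 - 3)
        assert dab % 2 == 0  # binary trees: symmetric difference is even

    @pytest.mark.parametrize("seed", range(15))
    def test_rerooting_invariance(self, seed):
        t1, t2 = random_tree(10, seed), random_tree(10, seed + 500)
        base = pc.rf_distance(t1, t2)
        d = dendropy.Tree.get(
            data=pc.write_newick(t1), schema="newick", preserve_underscores=True
        )
        edges = [e for e in d.edges() if e.tail_node is not None
                 and e.head_node is not d.seed_node]
        edge = edges[seed % len(edges)]
        d.reroot_at_edge(edge)
        rerooted = pc.parse_newick(
            d.as_string(schema="newick", unquoted_underscores=True)
        )
        assert pc.rf_distance(rerooted, t2) == base

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_dendropy(self, seed):
        t1, t2 = random_tree(12, seed + 40), random_tree(12, seed + 80)
        taxa = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=pc.write_newick(t1), schema="newick",
                               taxon_namespace=taxa, preserve_underscores=True)
        d2 = dendropy.Tree.get(data=pc.write_newick(t2), schema="newick",
                               taxon_namespace=taxa, preserve_underscores=True)
        expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert pc.rf_distance(t1, t2) == expected


class TestDistanceMatrix:
    def test_identical_trees_zero_matrix(self):
        t = random_tree(8, 3)
        dm = pc.distance_matrix([t, t])
        assert np.all(dm.values == 0)

    def test_symmetry_and_labels(self):
        trees = [random_tree(8, s) for s in range(4)]
        dm = pc.distance_matrix(trees, labels=list("wxyz"))
        assert dm.labels == list("wxyz")
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_mismatched_tips_rejected(self):
        with pytest.raises(ValueError):
            pc.distance_matrix([random_tree(8, 0), random_tree(9, 0)])


class TestPCoA:
    def test_two_points(self):
        dm = pc.DistanceMatrix(["a", "b"], np.array([[0.0, 6.0], [6.0, 0.0]]))
        res = pc.pcoa(dm)
        assert res.coordinates.shape == (2, 1)
        assert sorted(res.coordinates[:, 0]) == pytest.approx([-3.0, 3.0])
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_collinear_points_single_axis(self):
        xs = np.array([0.0, 1.0, 4.0, 9.0])
        d = np.abs(xs[:, None] - xs[None, :])
        res = pc.pcoa(pc.DistanceMatrix(list("abcd"), d))
        assert res.percent_variance[0] == pytest.approx(100.0)
        recon = pdist(res.coordinates[:, :1])
        assert recon == pytest.approx(pdist(xs[:, None]))

    def test_right_triangle_reconstructed(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        res = pc.pcoa(pc.DistanceMatrix(list("abc"), d))
        assert np.sum(res.eigenvalues > 0) == 2
        assert pdist(res.coordinates) == pytest.approx([3, 4, 5], abs=1e-9)
        assert not res.negative_eigenvalue_flag

    def test_percent_variance_sums_to_hundred(self):
        trees = [random_tree(10, s) for s in range(6)]
        res = pc.pcoa(pc.distance_matrix(trees))
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_sign_convention_reproducible(self):
        trees = [random_tree(10, s) for s in range(5)]
        dm = pc.distance_matrix(trees)
        a, b = pc.pcoa(dm), pc.pcoa(dm)
        assert np.array_equal(a.coordinates, b.coordinates)
        for k in range(a.coordinates.shape[1]):
            col = a.coordinates[:, k]
            assert col[np.argmax(np.abs(col))] >= 0

    def test_matches_scikit_bio(self):
        """Independent oracle: scikit-bio's PCoA on the same matrix must give
        the same eigenvalues and inter-point distances."""
        import warnings

        from skbio.stats.ordination import pcoa as skbio_pcoa

        trees = [random_tree(10, s + 60) for s in range(5)]
        dm = pc.distance_matrix(trees)
        ours = pc.pcoa(dm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            theirs = skbio_pcoa(dm.values, method="eigh")
        their_vals = np.sort(np.asarray(theirs.eigvals))[::-1]
        n_pos = ours.coordinates.shape[1]
        assert their_vals[:n_pos] == pytest.approx(
            ours.eigenvalues[:n_pos], rel=1e-8, abs=1e-8
        )
        their_coords = np.asarray(theirs.samples)[:, :n_pos]
        assert pdist(their_coords) == pytest.approx(pdist(ours.coordinates), abs=1e-6)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            pc.DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
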