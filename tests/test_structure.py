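import numpy as np
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import pdist, squareform

from cnvpop.cnvr import CnvRegion
from cnvpop.matrix import CnvMatrix, build_matrix
from cnvpop.structure import bootstrap_support, pca, sample_distances, upgma_tree


def _matrix(values, encoding="presence", samples=None):
    values = np.asarray(values)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    regions = [
        CnvRegion("1", 1000 * j + 1, 1000 * j + 500, "loss", frozenset({"x"}))
        for j in range(values.shape[1])
    ]
    return CnvMatrix(samples=samples, regions=regions, values=values, encoding=encoding)


def cophenetic(tree, labels):
    """Leaf-pair distances implied by the dendrogram (2 * merge height)."""
    n = len(labels)
    out = np.zeros((n, n))
    idx = {lab: i for i, lab in enumerate(labels)}
    for node in tree.internal_nodes():
        left, right = node.left.members, node.right.members
        for a in left:
            for b in right:
                out[idx[a], idx[b]] = out[idx[b], idx[a]] = 2 * node.height
    return out


class TestPca:
    def test_rank_one_matrix_pc1_explains_everything(self):
        result = pca(_matrix([[0], [1]]))
        assert result.variance_explained[0] == pytest.approx(1.0)

    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(6, 20))
        X[3] = X[0]
        result = pca(_matrix(X))
        np.testing.assert_allclose(result.coordinates[0], result.coordinates[3], atol=1e-10)

    def test_variance_explained_matches_covariance_eigenvalues(self):
        # oracle: eigenvalues of the sample covariance matrix, computed directly
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 50))
        result = pca(X)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(X.T, bias=True)))[::-1]
        expected = eigvals[:len(result.variance_explained)] / eigvals.sum()
        np.testing.assert_allclose(result.variance_explained, expected, atol=1e-10)

    def test_agrees_with_sklearn(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 30))
        result = pca(X)
        ref = sklearn.PCA().fit(X)
        np.testing.assert_allclose(
            result.variance_explained[:14], ref.explained_variance_ratio_[:14], atol=1e-10
        )

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 8))
        a, b = pca(X), pca(X + 7.5)
        np.testing.assert_allclose(np.abs(a.coordinates), np.abs(b.coordinates), atol=1e-9)
        np.testing.assert_allclose(a.variance_explained, b.variance_explained, atol=1e-12)

    def test_constant_matrix_flagged_degenerate(self):
        result = pca(_matrix(np.ones((5, 4), dtype=int)))
        assert result.degenerate
        assert np.all(result.variance_explained == 0)

    def test_variance_fractions_monotone_and_normalized(self):
        rng = np.random.default_rng(4)
        result = pca(rng.normal(size=(12, 40)))
        v = result.variance_explained
        assert np.all(np.diff(v) <= 1e-12)
        assert v.sum() == pytest.approx(1.0)


class TestUpgma:
    def test_three_taxon_hand_example(self):
        # d(A,B)=2, d(A,C)=d(B,C)=8: first merge (A,B) at height 1, root at 4
        D = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float)
        tree = upgma_tree(D, ["A", "B", "C"])
        assert tree.height == pytest.approx(4.0)
        first = tree.left if not tree.left.is_leaf else tree.right
        assert first.members == frozenset({"A", "B"})
        assert first.height == pytest.approx(1.0)

    def test_equal_distances_resolved_by_tie_break(self):
        D = np.ones((4, 4)) - np.eye(4)
        labels = ["d", "c", "b", "a"]
        tree = upgma_tree(D, labels)
        heights = sorted(n.height for n in tree.internal_nodes())
        assert heights == pytest.approx([0.5, 0.5, 0.5])
        # lexicographically smallest pair merges first regardless of input order
        smallest = min(
            (n for n in tree.internal_nodes() if len(n.members) == 2),
            key=lambda n: sorted(n.members),
        )
        assert smallest.members == frozenset({"a", "b"})

    def test_ultrametric_input_reproduced_exactly(self):
        # distances generated from a known ultrametric tree
        D = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]], dtype=float
        )
        labels = list("ABCD")
        tree = upgma_tree(D, labels)
        np.testing.assert_allclose(cophenetic(tree, labels), D, atol=1e-12)

    def test_matches_scipy_average_linkage(self):
        # independent oracle: scipy's average-linkage cophenetic distances are
        # exactly twice this dendrogram's merge heights
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 6))
        D = squareform(pdist(X))
        labels = [f"s{i}" for i in range(12)]
        tree = upgma_tree(D, labels)
        Z = average(pdist(X))
        np.testing.assert_allclose(
            cophenetic(tree, labels), squareform(cophenet(Z)), atol=1e-8
        )

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(8, 5))
        D = squareform(pdist(X))
        labels = [f"s{i}" for i in range(8)]
        perm = rng.permutation(8)
        tree1 = upgma_tree(D, labels)
        tree2 = upgma_tree(D[np.ix_(perm, perm)], [labels[i] for i in perm])
        assert tree1.clades() == tree2.clades()

    def test_nan_distance_rejected(self):
        D = np.zeros((2, 2))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            upgma_tree(D, ["a", "b"])

    def test_newick_parses_with_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        D = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float)
        tree = upgma_tree(D, ["A", "B", "C"])
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == {"A", "B", "C"}


def _two_breed_matrix(gap=0.8, n_per_pop=12, n_regions=24, seed=0):
    rng = np.random.default_rng(seed)
    base = 0.1
    X = np.zeros((2 * n_per_pop, n_regions), dtype=int)
    for j in range(n_regions):
        X[:n_per_pop, j] = rng.random(n_per_pop) < base + gap
        X[n_per_pop:, j] = rng.random(n_per_pop) < base
    samples = [f"A{i}" for i in range(n_per_pop)] + [f"B{i}" for i in range(n_per_pop)]
    return _matrix(X, samples=samples), samples


class TestBootstrap:
    def test_true_breed_split_has_high_support(self):
        matrix, samples = _two_breed_matrix(gap=0.8)
        tree = bootstrap_support(matrix, n_boot=200, seed=1)
        split = frozenset(s for s in samples if s.startswith("A"))
        supports = {n.members: n.support for n in tree.internal_nodes()}
        assert split in supports or frozenset(samples) - split in supports
        bp = supports.get(split, supports.get(frozenset(samples) - split))
        assert bp >= 0.95

    def test_single_replicate_gives_binary_support(self):
        matrix, _ = _two_breed_matrix(n_per_pop=5, n_regions=10)
        tree = bootstrap_support(matrix, n_boot=1, seed=3)
        assert all(n.support in (0.0, 1.0) for n in tree.internal_nodes())

    def test_column_permutation_leaves_support_unchanged(self):
        matrix, _ = _two_breed_matrix(n_per_pop=6, n_regions=12)
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(matrix.regions))
        shuffled = CnvMatrix(
            samples=matrix.samples,
            regions=[matrix.regions[i] for i in perm],
            values=matrix.values[:, perm],
            encoding=matrix.encoding,
        )
        t1 = bootstrap_support(matrix, n_boot=50, seed=5)
        t2 = bootstrap_support(shuffled, n_boot=50, seed=5)
        assert {(n.members, n.support) for n in t1.internal_nodes()} == \
               {(n.members, n.support) for n in t2.internal_nodes()}


def test_jaccard_distance_on_copy_number_uses_carrier_indicator():
    cn = _matrix([[2, 3, 2], [2, 0, 2], [2, 2, 4]], encoding="copy_number")
    D = sample_distances(cn, metric="jaccard")
    # samples 0 and 1 carry the same single region -> distance 0
    assert D[0, 1] == pytest.approx(0.0)
    assert D[0, 2] == pytest.approx(1.0)
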