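"""Population-structure summaries on a CNV matrix.

* PCA on the centered individual x CNVR matrix (singular value
  decomposition; no column scaling), reporting the variance fraction each
  component explains.
* Pairwise sample distances (Euclidean by default, Jaccard for
  presence/absence matrices).
* UPGMA agglomerative clustering into a rooted ultrametric dendrogram, with
  deterministic lexicographic tie-breaking so reruns are identical.
* Ordinary bootstrap support: CNVR columns are resampled with replacement,
  the tree is rebuilt, and each internal node of the reference tree gets the
  fraction of replicates containing the same leaf clade (BP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from cnvpop.matrix import CnvMatrix


@dataclass
class PcaResult:
    sample_ids: list[str]
    coordinates: np.ndarray      # samples x components
    variance_explained: np.ndarray
    degenerate: bool = False     # constant input: no variance to decompose


@dataclass
class TreeNode:
    """Node of a rooted ultrametric dendrogram; leaves carry a sample label."""

    height: float
    members: frozenset[str]
    label: str | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    support: float | None = None  # bootstrap proportion, internal nodes only

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def internal_nodes(self) -> list["TreeNode"]:
        if self.is_leaf:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes (the tree's clade system)."""
        return {n.members for n in self.internal_nodes()}

    def to_newick(self, with_support: bool = False) -> str:
        def fmt(node: TreeNode, parent_height: float) -> str:
            branch = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{branch:.6g}"
            inner = f"({fmt(node.left, node.height)},{fmt(node.right, node.height)})"
            sup = ""
            if with_support and node.support is not None:
                sup = f"{node.support:.3g}"
            return f"{inner}{sup}:{branch:.6g}"

        if self.is_leaf:
            return f"{self.label}:0;"
        inner = f"({fmt(self.left, self.height)},{fmt(self.right, self.height)})"
        sup = f"{self.support:.3g}" if with_support and self.support is not None else ""
        return f"{inner}{sup};"


def pca(matrix: CnvMatrix | np.ndarray, sample_ids: Sequence[str] | None = None) -> PcaResult:
    """PCA of the centered matrix; variance_explained_i = lambda_i / sum(lambda).

    Columns are centered but not scaled, so a constant column (a region every
    sample carries identically) contributes nothing.  A fully constant matrix
    has no principal axes; the result is flagged degenerate with all-zero
    variance fractions.
    """
    if isinstance(matrix, CnvMatrix):
        X = matrix.values.astype(float)
        ids = list(matrix.samples)
    else:
        X = np.asarray(matrix, dtype=float)
        ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(len(X))]
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("PCA needs >= 2 samples and >= 1 region")

    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        k = min(Xc.shape)
        return PcaResult(ids, np.zeros((len(ids), k)), np.zeros(k), degenerate=True)
    return PcaResult(ids, U * s, s**2 / total, degenerate=False)


def sample_distances(matrix: CnvMatrix, metric: str = "euclidean") -> np.ndarray:
    """Square symmetric pairwise distance matrix over samples."""
    X = matrix.values.astype(float)
    if metric == "jaccard" and matrix.encoding != "presence":
        X = (matrix.values != 2).astype(float)
    return squareform(pdist(X, metric=metric))


def upgma_tree(distances: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """UPGMA agglomeration with average linkage and lexicographic tie-breaks.

    Merge height is half the mean inter-cluster distance, so leaf-to-leaf
    path length through the merge node reproduces the (ultrametric part of
    the) input.  Among equally close pairs the one whose sorted member-label
    tuples are lexicographically smallest merges first, which pins the tree
    topology for any input order.
    """
    D = np.asarray(distances, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if n == 1:
        return TreeNode(height=0.0, members=frozenset(labels), label=labels[0])

    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, members=frozenset([lab]), label=lab)
        for i, lab in enumerate(labels)
    }
    sizes = {i: 1 for i in range(n)}
    keys = {i: tuple(sorted(nodes[i].members)) for i in range(n)}
    dist = {(i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)}
    next_id = n

    while len(nodes) > 1:
        # smallest distance; ties broken on sorted member labels
        (i, j) = min(
            dist,
            key=lambda p: (dist[p], *sorted((keys[p[0]], keys[p[1]]))),
        )
        d_ij = dist.pop((i, j))
        merged = TreeNode(
            height=d_ij / 2.0,
            members=nodes[i].members | nodes[j].members,
            left=nodes[i] if keys[i] <= keys[j] else nodes[j],
            right=nodes[j] if keys[i] <= keys[j] else nodes[i],
        )
        new_size = sizes[i] + sizes[j]
        new_dists = {}
        for k in nodes:
            if k in (i, j):
                continue
            d_ik = dist.pop((min(i, k), max(i, k)))
            d_jk = dist.pop((min(j, k), max(j, k)))
            new_dists[k] = (sizes[i] * d_ik + sizes[j] * d_jk) / new_size
        del nodes[i], nodes[j], sizes[i], sizes[j], keys[i], keys[j]
        nodes[next_id] = merged
        sizes[next_id] = new_size
        keys[next_id] = tuple(sorted(merged.members))
        for k, d in new_dists.items():
            dist[(min(k, next_id), max(k, next_id))] = d
        next_id += 1

    return nodes.popitem()[1]


def bootstrap_support(
    matrix: CnvMatrix,
    n_boot: int,
    seed: int,
    metric: str = "euclidean",
) -> TreeNode:
    """Reference UPGMA tree with per-node bootstrap proportions.

    Regions (columns) are resampled with replacement ``n_boot`` times; each
    internal node's support is the fraction of replicate trees containing
    the identical leaf clade.  Columns are put in a canonical (region id)
    order before drawing, so column permutation of the input does not change
    the replicate stream.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    order = np.argsort([r.region_id for r in matrix.regions], kind="stable")
    X = matrix.values[:, order].astype(float)
    labels = list(matrix.samples)

    ref = upgma_tree(squareform(pdist(X, metric=metric)), labels)
    counts = {node.members: 0 for node in ref.internal_nodes()}

    rng = np.random.default_rng(seed)
    n_regions = X.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, n_regions, size=n_regions)
        rep = upgma_tree(squareform(pdist(X[:, cols], metric=metric)), labels)
        for clade in rep.clades():
            if clade in counts:
                counts[clade] += 1
    for node in ref.internal_nodes():
        node.support = counts[node.members] / n_boot
    return ref
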