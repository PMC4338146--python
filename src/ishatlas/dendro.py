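"""Tissue dendrograms from rank correlations of ordinal expression profiles.

Pipeline: ordinally encoded annotation grid -> tissue x tissue Spearman
rank correlation (pairwise-complete over genes, average ranks for ties) ->
dissimilarity ``d = 1 - rho`` -> unrooted distance tree by canonical
neighbor joining -> Newick.

Neighbor joining is statistically consistent for additive distances: when
``d`` is exactly the path-length metric of some tree, that tree (topology
and branch lengths) is recovered exactly.  Negative branch-length estimates,
which NJ can produce on non-additive input, are clamped to zero.
"""
from __future__ import annotations

import dataclasses
import io
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from skbio import TreeNode


def spearman_matrix(encoded: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Tissue x tissue Spearman rank correlation of an encoded grid.

    Parameters
    ----------
    encoded:
        Gene x tissue numeric grid with NaN marking not-analyzed cells
        (the output of :func:`ishatlas.annotation.encode_ordinal`).
    min_shared:
        Minimum number of genes unmasked in *both* tissues of a pair.

    For each tissue pair only genes unmasked in both columns enter the
    correlation (pairwise-complete); ties get average ranks.  Raises
    ``ValueError`` naming the first pair with fewer than `min_shared`
    shared genes.
    """
    labels = list(encoded.columns)
    values = encoded.to_numpy(dtype=float)
    n = len(labels)
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~np.isnan(values[:, i]) & ~np.isnan(values[:, j])
            if mask.sum() < min_shared:
                raise ValueError(
                    f"tissues {labels[i]!r} and {labels[j]!r} share only "
                    f"{int(mask.sum())} analyzed genes (need >= {min_shared})"
                )
            rho = spearmanr(values[mask, i], values[mask, j]).statistic
            corr[i, j] = corr[j, i] = rho
    return pd.DataFrame(corr, index=labels, columns=labels)


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative dissimilarity matrix with a zero diagonal."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(frame.columns), frame.to_numpy(dtype=float))


def to_distance(corr: pd.DataFrame) -> DistanceMatrix:
    """Correlation -> dissimilarity, ``d = 1 - rho`` with a zero diagonal."""
    d = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # remove floating asymmetry from the correlation pass
    return DistanceMatrix(tuple(corr.columns), d)


class TissueTree:
    """Unrooted branch-length tree over tissue labels (scikit-bio backed).

    The underlying representation is a :class:`skbio.TreeNode` whose root
    is the final unresolved trifurcation of neighbor joining; the tree is
    to be interpreted as unrooted.
    """

    def __init__(self, root: TreeNode) -> None:
        self.root = root

    @property
    def leaf_names(self) -> set:
        return {t.name for t in self.root.tips()}

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.root.write(buf)
        return buf.getvalue().strip()

    @classmethod
    def from_newick(cls, text: str) -> "TissueTree":
        return cls(TreeNode.read(io.StringIO(text)))

    def robinson_foulds(self, other: "TissueTree") -> float:
        """Unrooted Robinson-Foulds (symmetric bipartition) distance."""
        return float(self.root.compare_rfd(other.root))

    def tip_distances(self) -> DistanceMatrix:
        """Path-length metric between all leaf pairs."""
        dm = self.root.tip_tip_distances()
        labels = tuple(dm.ids)
        return DistanceMatrix(labels, np.asarray(dm.data, dtype=float))

    def __repr__(self) -> str:
        return f"<TissueTree {len(self.leaf_names)} leaves>"


def build_tree(dist: DistanceMatrix) -> TissueTree:
    """Canonical neighbor joining on a distance matrix.

    Agglomeration picks the pair minimizing the Q criterion
    ``Q(i,j) = (n-2) d(i,j) - r_i - r_j``; on exact ties the lowest
    (row, column) index pair wins, making the output deterministic.
    Branch-length estimates below zero are clamped to zero.  The result is
    an unrooted tree represented with a trifurcating root (for >= 3 taxa).
    """
    labels = list(dist.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two labels to build a tree")
    d = dist.values.astype(float).copy()
    nodes = [TreeNode(name=lab) for lab in labels]

    if n == 2:
        for node in nodes:
            node.length = max(d[0, 1] / 2.0, 0.0)
        return TissueTree(TreeNode(children=nodes))

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # first minimum in row-major order
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0])
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = (d[i, ak] + d[j, ak] - dij) / 2.0
        d = np.vstack([d, new_row[None, :]])
        new_col = np.append(new_row, 0.0)
        d = np.hstack([d, new_col[:, None]])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    # terminal star: three branches meeting at the trifurcating root
    li = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2.0
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(ln, 0.0)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return TissueTree(root)


def to_newick(tree: TissueTree) -> str:
    """Newick serialization with branch lengths."""
    return tree.to_newick()


def tissue_tree(
    encoded: pd.DataFrame, min_shared: int = 3
) -> tuple[TissueTree, DistanceMatrix]:
    """Convenience: encoded grid -> (NJ tree, Spearman distance matrix)."""
    corr = spearman_matrix(encoded, min_shared=min_shared)
    dist = to_distance(corr)
    return build_tree(dist), dist


def is_monophyletic_unrooted(tree: TissueTree, labels) -> bool:
    """True if `labels` form one side of some split of the unrooted tree.

    A singleton or the full leaf set is trivially monophyletic.
    """
    target = frozenset(labels)
    tips = frozenset(tree.leaf_names)
    if not target <= tips:
        raise ValueError("labels are not a subset of the tree's leaves")
    if len(target) <= 1 or target == tips:
        return True
    for node in tree.root.traverse(include_self=False):
        clade = frozenset(t.name for t in node.tips()) or frozenset({node.name})
        if clade == target or (tips - clade) == target:
            return True
    return False


def cut_tree(tree: TissueTree, k: int) -> list[set]:
    """Partition the leaves into `k` groups by removing the k-1 longest
    internal branches.

    This is a simple longest-branch heuristic offered as a labelled
    approximation to model-based dendrogram partitioning; it is not a
    reimplementation of any published partitioning program.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tmp = TissueTree.from_newick(tree.to_newick())  # work on a copy
    internal = [
        node
        for node in tmp.root.traverse(include_self=False)
        if not node.is_tip() and node.length is not None
    ]
    internal.sort(key=lambda nd: (-(nd.length or 0.0), min(t.name for t in nd.tips())))
    to_cut = internal[: k - 1]
    groups: list[set] = []
    cut_set = set(id(nd) for nd in to_cut)

    def collect(node, bucket: set) -> None:
        for child in node.children:
            if id(child) in cut_set:
                continue
            if child.is_tip():
                bucket.add(child.name)
            else:
                collect(child, bucket)

    roots = [tmp.root] + to_cut
    for rt in roots:
        bucket: set = set()
        collect(rt, bucket)
        if rt.is_tip():
            bucket.add(rt.name)
        if bucket:
            groups.append(bucket)
    return sorted(groups, key=lambda s: (-len(s), min(s)))
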