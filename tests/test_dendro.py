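"""Spearman matrices, distance transforms and neighbor-joining trees."""
from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio import TreeNode

from ishatlas.dendro import (
    DistanceMatrix,
    TissueTree,
    build_tree,
    cut_tree,
    is_monophyletic_unrooted,
    spearman_matrix,
    to_distance,
    to_newick,
)


# -- independent oracles ---------------------------------------------------

def average_ranks(values: np.ndarray) -> np.ndarray:
    """Hand-written average ranking (1-based, ties share the mean rank)."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def naive_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-then-Pearson on pairwise-complete observations."""
    mask = ~np.isnan(x) & ~np.isnan(y)
    rx, ry = average_ranks(x[mask]), average_ranks(y[mask])
    return float(np.corrcoef(rx, ry)[0, 1])


def random_additive_tree(rng: np.random.Generator, n_taxa: int) -> TissueTree:
    """Random unrooted binary tree with positive branch lengths."""
    nodes = [TreeNode(name=f"L{i}") for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        for x in (a, b):
            x.length = float(rng.uniform(0.5, 5.0))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(TreeNode(children=[a, b]))
    for nd in nodes:
        nd.length = float(rng.uniform(0.5, 5.0))
    return TissueTree(TreeNode(children=nodes))


def tree_splits(tree: TissueTree) -> set:
    """Non-trivial bipartitions of the unrooted tree, side-normalized."""
    tips = frozenset(tree.leaf_names)
    splits = set()
    for node in tree.root.traverse(include_self=False):
        if node.is_tip():
            continue
        clade = frozenset(t.name for t in node.tips())
        if 1 < len(clade) < len(tips) - 1:
            splits.add(frozenset({clade, tips - clade}))
    return splits


def enumerate_unrooted_topologies(labels: list) -> list:
    """All unrooted binary topologies over `labels` as networkx graphs."""
    first = nx.Graph()
    center = "int0"
    first.add_edges_from((center, lab) for lab in labels[:3])
    trees = [first]
    for idx, lab in enumerate(labels[3:], start=1):
        grown = []
        for tree in trees:
            for edge in list(tree.edges):
                t2 = tree.copy()
                u, v = edge
                w = f"int{idx}_{u}_{v}"
                t2.remove_edge(u, v)
                t2.add_edges_from([(u, w), (w, v), (w, lab)])
                grown.append(t2)
        trees = grown
    return trees


def graph_splits(tree: nx.Graph, labels: list) -> set:
    tips = frozenset(labels)
    splits = set()
    for u, v in tree.edges:
        t2 = tree.copy()
        t2.remove_edge(u, v)
        side = frozenset(n for n in nx.node_connected_component(t2, u) if n in tips)
        if 1 < len(side) < len(tips) - 1:
            splits.add(frozenset({side, tips - side}))
    return splits


def minimum_evolution_topology(dist: DistanceMatrix) -> set:
    """Exhaustive OLS minimum-evolution search; returns the winning splits.

    For every unrooted topology, branch lengths are the ordinary
    least-squares fit to the pairwise distances and the score is the total
    tree length; the minimum-length topology wins.
    """
    labels = list(dist.labels)
    index = {lab: i for i, lab in enumerate(labels)}
    best = None
    best_len = np.inf
    for tree in enumerate_unrooted_topologies(labels):
        edges = list(tree.edges)
        rows, targets = [], []
        for a, b in itertools.combinations(labels, 2):
            path = nx.shortest_path(tree, a, b)
            on_path = set(zip(path, path[1:])) | set(zip(path[1:], path))
            rows.append([1.0 if e in on_path or e[::-1] in on_path else 0.0
                         for e in edges])
            targets.append(dist.values[index[a], index[b]])
        lengths, *_ = np.linalg.lstsq(np.array(rows), np.array(targets), rcond=None)
        total = float(lengths.sum())
        if total < best_len - 1e-10:
            best_len = total
            best = graph_splits(tree, labels)
    return best


# -- spearman --------------------------------------------------------------

class TestSpearman:
    def test_identical_columns_give_one(self):
        col = np.array([0, 2, 3, 4, 0, 2.0])
        frame = pd.DataFrame({"A": col, "B": col})
        corr = spearman_matrix(frame)
        assert corr.loc["A", "B"] == pytest.approx(1.0)

    def test_perfect_reversal_gives_minus_one(self):
        frame = pd.DataFrame({"A": [0, 2, 3, 4.0], "B": [4, 3, 2, 0.0]})
        assert spearman_matrix(frame).loc["A", "B"] == pytest.approx(-1.0)

    def test_matches_naive_rank_then_pearson_with_ties_and_nans(self, rng):
        x = rng.choice([0.0, 2.0, 3.0, 4.0, np.nan], size=30, p=[0.4, 0.3, 0.15, 0.1, 0.05])
        y = rng.choice([0.0, 2.0, 3.0, 4.0, np.nan], size=30, p=[0.3, 0.3, 0.2, 0.15, 0.05])
        frame = pd.DataFrame({"A": x, "B": y})
        got = spearman_matrix(frame).loc["A", "B"]
        assert got == pytest.approx(naive_spearman(x, y), abs=1e-12)

    def test_too_few_shared_genes_errors_naming_pair(self):
        frame = pd.DataFrame(
            {"A": [0.0, 2.0, np.nan, np.nan], "B": [np.nan, 2.0, 3.0, 4.0]}
        )
        with pytest.raises(ValueError, match="'A' and 'B'"):
            spearman_matrix(frame)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_strictly_monotone_recoding(self, seed):
        # the 0/2/3/4 vs 0/1/2/3 choice cannot change rho when masks agree
        rng = np.random.default_rng(seed)
        base = rng.choice([0.0, 2.0, 3.0, 4.0], size=(25, 3))
        frame = pd.DataFrame(base, columns=["A", "B", "C"])
        recoded = frame.replace({0.0: 0.0, 2.0: 1.0, 3.0: 2.0, 4.0: 3.0})
        c1, c2 = spearman_matrix(frame), spearman_matrix(recoded)
        assert np.allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-12)


class TestDistance:
    @pytest.mark.parametrize("rho,expected", [(1.0, 0.0), (-1.0, 2.0), (0.5, 0.5)])
    def test_one_minus_rho(self, rho, expected):
        corr = pd.DataFrame([[1.0, rho], [rho, 1.0]], index=["A", "B"], columns=["A", "B"])
        dist = to_distance(corr)
        assert dist.values[0, 1] == pytest.approx(expected)
        assert dist.values[0, 0] == 0.0

    def test_validation_rejects_asymmetry_and_negatives(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="non-negative"):
            DistanceMatrix(("A", "B"), np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_tsv_round_trip(self, tmp_path):
        dm = DistanceMatrix(("A", "B", "C"),
                            np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]]))
        dm.write_tsv(tmp_path / "d.tsv")
        again = DistanceMatrix.read_tsv(tmp_path / "d.tsv")
        assert again.labels == dm.labels
        assert np.allclose(again.values, dm.values)


class TestBuildTree:
    def test_four_taxon_exact_recovery_known_lengths(self):
        # ((A:1,B:2):5,C:3,D:4) — internal branch 5, tip branches 1..4
        a, b, c, d = (TreeNode(name=n) for n in "ABCD")
        a.length, b.length, c.length, d.length = 1.0, 2.0, 3.0, 4.0
        ab = TreeNode(children=[a, b])
        ab.length = 5.0
        true = TissueTree(TreeNode(children=[ab, c, d]))
        recovered = build_tree(true.tip_distances())
        assert true.robinson_foulds(recovered) == 0.0
        got = recovered.tip_distances()
        want = true.tip_distances()
        order = [got.labels.index(l) for l in want.labels]
        assert np.allclose(want.values, got.values[np.ix_(order, order)], atol=1e-10)

    def test_three_identical_tissues_co_cluster(self):
        labels = ("A", "B", "C", "Z")
        d = np.array(
            [
                [0.0, 0.0, 0.0, 9.0],
                [0.0, 0.0, 0.0, 9.0],
                [0.0, 0.0, 0.0, 9.0],
                [9.0, 9.0, 9.0, 0.0],
            ]
        )
        tree = build_tree(DistanceMatrix(labels, d))
        assert is_monophyletic_unrooted(tree, {"A", "B", "C"})

    def test_equals_exhaustive_minimum_evolution_on_five_taxa(self, rng):
        for _ in range(5):
            true = random_additive_tree(rng, 5)
            dist = true.tip_distances()
            nj_splits = tree_splits(build_tree(dist))
            me_splits = minimum_evolution_topology(dist)
            assert nj_splits == me_splits

    def test_additive_recovery_across_sizes(self, rng):
        for n_taxa in (4, 5, 6, 7, 8):
            true = random_additive_tree(rng, n_taxa)
            dist = true.tip_distances()
            recovered = build_tree(dist)
            assert true.robinson_foulds(recovered) == 0.0
            got = recovered.tip_distances()
            order = [got.labels.index(l) for l in dist.labels]
            assert np.allclose(dist.values, got.values[np.ix_(order, order)], atol=1e-9)

    def test_negative_branch_estimates_clamped(self, rng):
        # non-additive noisy matrix must still yield non-negative lengths
        n = 6
        noise = rng.uniform(0.0, 1.0, size=(n, n))
        d = noise + noise.T
        np.fill_diagonal(d, 0.0)
        tree = build_tree(DistanceMatrix(tuple("ABCDEF"), d))
        for node in tree.root.traverse(include_self=False):
            assert node.length is not None and node.length >= 0.0


class TestNewick:
    def test_three_leaf_star_form(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = build_tree(DistanceMatrix(("A", "B", "C"), d))
        text = to_newick(tree)
        assert text.endswith(";")
        reparsed = TissueTree.from_newick(text)
        assert reparsed.leaf_names == {"A", "B", "C"}

    def test_round_trip_is_isomorphic(self, rng):
        tree = random_additive_tree(rng, 8)
        again = TissueTree.from_newick(to_newick(tree))
        assert tree.robinson_foulds(again) == 0.0

    def test_25_leaf_round_trip_rf_zero(self, rng):
        tree = random_additive_tree(rng, 25)
        again = TissueTree.from_newick(to_newick(tree))
        assert tree.robinson_foulds(again) == 0.0


class TestNeighborJoiningCrossCheck:
    def test_matches_reference_nj_engine_on_random_additive_input(self, rng):
        """Independent route: scikit-bio's own NJ on the same matrix."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        for _ in range(5):
            true = random_additive_tree(rng, 7)
            dist = true.tip_distances()
            ours = build_tree(dist)
            theirs = TissueTree(
                skbio_nj(SkbioDM(dist.values, ids=list(dist.labels)))
            )
            assert ours.robinson_foulds(theirs) == 0.0


class TestCutTree:
    def test_partitions_leaves_into_k_groups(self, rng):
        tree = random_additive_tree(rng, 10)
        groups = cut_tree(tree, 3)
        assert len(groups) == 3
        union = set().union(*groups)
        assert union == tree.leaf_names
        assert sum(len(g) for g in groups) == 10
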