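"""Neighbor joining, patristic nearest relative, RPKM and transcript ratios."""

import math

import networkx as nx
import numpy as np
import pytest

from pamg.phylo import (
    GeneTree,
    TranscriptRatioRecord,
    nearest_relative,
    nj_tree,
    poisson_distance,
    protein_distance_matrix,
    ratio_summary,
    rpkm,
)


def tree_to_graph(tree: GeneTree) -> nx.Graph:
    g = nx.Graph()
    for u, edges in tree.adjacency.items():
        for v, w in edges:
            g.add_edge(u, v, weight=w)
    return g


def patristic_oracle(tree: GeneTree, a: str, b: str) -> float:
    return nx.dijkstra_path_length(tree_to_graph(tree), a, b)


class TestNJ:
    def test_three_taxa_closed_form(self):
        # d(A,B)=3, d(A,C)=4, d(B,C)=5 -> star with la=1, lb=2, lc=3
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(D, ["A", "B", "C"])
        for a, b, exp in [("A", "B", 3), ("A", "C", 4), ("B", "C", 5)]:
            assert patristic_oracle(tree, a, b) == pytest.approx(exp)

    def test_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): all pairwise path lengths reproduced
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(D, labels)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert patristic_oracle(tree, a, b) == pytest.approx(D[i, j])
        # AB|CD split: A and B share their nearest internal node
        g = tree_to_graph(tree)
        (na,) = g[("A")]
        (nb,) = g[("B")]
        assert na == nb

    def test_asymmetric_matrix_errors(self):
        D = np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(D, list("ABC"))

    def test_nonzero_diagonal_errors(self):
        D = np.array([[1, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(D, list("ABC"))

    def test_negative_entry_errors(self):
        D = np.array([[0, -1, 2], [-1, 0, 3], [2, 3, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(D, list("ABC"))

    def test_too_few_taxa_errors(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), list("AB"))

    def test_no_negative_branch_lengths(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 6
            X = rng.random((n, 4))
            D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
            tree = nj_tree(D, [f"t{i}" for i in range(n)])
            for u, edges in tree.adjacency.items():
                for _, w in edges:
                    assert w >= 0


def random_gene_tree(rng, n_leaves):
    """Random topology by sequential joining, random branch lengths."""
    tree = GeneTree()
    nodes = []
    for i in range(n_leaves):
        role = "bacterial" if rng.random() < 0.5 else "phage"
        name = f"{role[0]}{i}"
        tree.leaf_roles[name] = role
        tree.adjacency.setdefault(name, [])
        nodes.append(name)
    k = 0
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        u = f"i{k}"
        k += 1
        tree.add_edge(u, a, float(rng.uniform(0, 2)))
        tree.add_edge(u, b, float(rng.uniform(0, 2)))
        nodes = [x for x in nodes if x not in (a, b)] + [u]
    return tree


class TestNearestRelative:
    def test_bacterial_sister_is_chosen(self):
        tree = GeneTree(leaf_roles={"p1": "phage", "b1": "bacterial", "b2": "bacterial"})
        tree.add_edge("x", "p1", 0.1)
        tree.add_edge("x", "b1", 0.1)
        tree.add_edge("x", "b2", 5.0)
        assert nearest_relative(tree, "p1") == "b1"

    def test_matches_bruteforce_on_random_trees(self):
        rng = np.random.default_rng(99)
        n_checked = 0
        for _ in range(200):
            tree = random_gene_tree(rng, int(rng.integers(4, 10)))
            bacterial = [l for l, r in tree.leaf_roles.items() if r == "bacterial"]
            phage = [l for l, r in tree.leaf_roles.items() if r == "phage"]
            if not bacterial or not phage:
                continue
            for focal in phage:
                expected = min(
                    (patristic_oracle(tree, focal, b), b) for b in bacterial
                )[1]
                assert nearest_relative(tree, focal) == expected
                n_checked += 1
        assert n_checked > 100

    def test_no_bacterial_leaf_gives_none(self):
        tree = GeneTree(leaf_roles={"p1": "phage", "p2": "phage", "p3": "phage"})
        tree.add_edge("x", "p1", 1.0)
        tree.add_edge("x", "p2", 1.0)
        tree.add_edge("x", "p3", 1.0)
        assert nearest_relative(tree, "p1") is None

    def test_unknown_leaf_errors(self):
        tree = GeneTree(leaf_roles={"p1": "phage"})
        tree.adjacency["p1"] = []
        with pytest.raises(KeyError):
            nearest_relative(tree, "zzz")


class TestDistances:
    def test_poisson_correction(self):
        assert poisson_distance(0.0) == 0.0
        assert poisson_distance(0.5) == pytest.approx(math.log(2))
        with pytest.raises(ValueError):
            poisson_distance(1.0)

    def test_matrix_is_symmetric_zero_diagonal(self):
        seqs = {"a": "MKKLVWYPHA", "b": "MKKLVWYPHG", "c": "MKWLVAYPHG"}
        D, labels = protein_distance_matrix(seqs)
        assert labels == ["a", "b", "c"]
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)


class TestRpkm:
    def test_arithmetic(self):
        assert rpkm(100, 1000, 10**6) == pytest.approx(100.0)

    def test_zero_reads(self):
        assert rpkm(0, 1000, 10**6) == 0.0

    def test_linearity(self):
        base = rpkm(50, 800, 2_000_000)
        assert rpkm(100, 800, 2_000_000) == pytest.approx(2 * base)
        assert rpkm(50, 1600, 2_000_000) == pytest.approx(base / 2)
        assert rpkm(50, 800, 4_000_000) == pytest.approx(base / 2)

    @pytest.mark.parametrize("gene_len,total", [(0, 10**6), (1000, 0)])
    def test_degenerate_inputs_error(self, gene_len, total):
        with pytest.raises(ValueError):
            rpkm(10, gene_len, total)


class TestRatioSummary:
    def test_22_of_48(self):
        records = [
            TranscriptRatioRecord(f"p{i}", 2.0, 1.0) for i in range(22)
        ] + [TranscriptRatioRecord(f"q{i}", 0.5, 1.0) for i in range(26)]
        s = ratio_summary(records)
        assert s["n_recorded"] == 48
        assert s["n_gt_one"] == 22
        assert s["fraction_gt_one"] == pytest.approx(22 / 48)

    def test_ratio_exactly_one_not_counted(self):
        records = [TranscriptRatioRecord("p", 1.0, 1.0)]
        assert ratio_summary(records)["n_gt_one"] == 0

    def test_infinite_ratio_counts_as_greater_than_one(self):
        rec = TranscriptRatioRecord("p", 0.5, 0.0)
        assert rec.ratio == math.inf
        assert ratio_summary([rec])["n_gt_one"] == 1

    def test_silent_pairs_not_recorded(self):
        records = [
            TranscriptRatioRecord("p", 0.0, 0.0),
            TranscriptRatioRecord("q", 2.0, 1.0),
        ]
        assert records[0].ratio is None
        assert ratio_summary(records)["n_recorded"] == 1

    def test_all_silent_errors(self):
        with pytest.raises(ValueError):
            ratio_summary([TranscriptRatioRecord("p", 0.0, 0.0)])
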