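"""p-distances, neighbor-joining correctness, bootstrap support."""

import itertools

import numpy as np
import pytest

from stescan import (
    DistanceMatrix,
    bootstrap_support,
    neighbor_joining,
    p_distance_matrix,
)
from stescan.phylogeny import bipartitions


def build_additive(n_taxa, rng):
    """Random additive matrix via explicit tree simulation on a leaf walk."""
    labels = [f"t{i:02d}" for i in range(n_taxa)]
    # grow an unrooted tree edge list by attaching leaves to random edges
    # nodes: 0..; edges: dict (u,v)->length
    edges = {}
    next_node = [n_taxa]

    def add_edge(u, v, w):
        edges[(u, v)] = w

    # start from a 3-star
    center = next_node[0]
    next_node[0] += 1
    for i in range(3):
        add_edge(center, i, rng.uniform(0.05, 0.5))
    for leaf in range(3, n_taxa):
        # split a random existing edge with a new internal node, hang the leaf
        (u, v), w = list(edges.items())[rng.integers(len(edges))]
        del edges[(u, v)]
        mid = next_node[0]
        next_node[0] += 1
        a = rng.uniform(0.2, 0.8) * w
        add_edge(u, mid, a)
        add_edge(mid, v, w - a)
        add_edge(mid, leaf, rng.uniform(0.05, 0.5))
    # all-pairs leaf distances by BFS over the tree
    adj = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    dist = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, w in adj[node]:
                if nb not in seen:
                    seen[nb] = seen[node] + w
                    stack.append(nb)
        for dst in range(n_taxa):
            dist[src, dst] = seen[dst]
    # true bipartitions: remove each internal edge
    ref = labels[0]
    splits = set()
    for (u, v) in edges:
        if u < n_taxa or v < n_taxa:
            continue  # pendant edges and the star edges give trivial splits
        side = _component_leaves(adj, u, v, n_taxa)
        if 2 <= len(side) <= n_taxa - 2:
            names = frozenset(labels[i] for i in side)
            if ref in names:
                names = frozenset(set(labels) - names)
            splits.add(names)
    # edges between internal node and leaf-side internal node handled above;
    # also internal-to-internal edges where one endpoint is the center
    return labels, dist, splits


def _component_leaves(adj, start, blocked, n_taxa):
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for nb, _ in adj[node]:
            if nb != blocked and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return {x for x in seen if x < n_taxa}


class TestPDistance:
    def test_identical(self):
        dm = p_distance_matrix([("a", "ACGTACGTAC"), ("b", "ACGTACGTAC")])
        assert dm.matrix[0, 1] == 0.0

    def test_one_in_ten(self):
        dm = p_distance_matrix([("a", "ACGTACGTAC"), ("b", "ACGTACGTAT")])
        assert dm.matrix[0, 1] == pytest.approx(0.1)
        assert dm.comparable[0, 1] == 10

    def test_pairwise_deletion(self):
        dm = p_distance_matrix([("a", "AC-T"), ("b", "ACGT")])
        assert dm.comparable[0, 1] == 3
        assert dm.matrix[0, 1] == 0.0

    def test_ambiguity_deleted(self):
        dm = p_distance_matrix([("a", "ACNT"), ("b", "ACGA")])
        assert dm.comparable[0, 1] == 3
        assert dm.matrix[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_sites(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance_matrix([("a", "--AC"), ("b", "GT--")])

    def test_unaligned_input(self):
        with pytest.raises(ValueError, match="aligned"):
            p_distance_matrix([("a", "ACG"), ("b", "AC")])

    def test_pseudometric_on_gap_free_triples(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        for _ in range(20):
            seqs = ["".join(rng.choice(bases, 50)) for _ in range(3)]
            dm = p_distance_matrix(list(zip("abc", seqs))).matrix
            assert np.allclose(dm, dm.T)
            assert np.all(np.diag(dm) == 0)
            for i, j, k in itertools.permutations(range(3)):
                assert dm[i, j] <= dm[i, k] + dm[k, j] + 1e-12


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        m = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        tree = neighbor_joining(DistanceMatrix(list("abc"), m, np.ones((3, 3), int)))
        lengths = {t.name: t.branch_length for t in tree.get_terminals()}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.3)
        assert lengths["c"] == pytest.approx(0.5)

    def test_fewer_than_three_taxa(self):
        m = np.array([[0, 0.1], [0.1, 0]])
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], m, np.ones((2, 2), int)))

    def test_four_taxon_additive_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) with internal edge 1
        m = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(list("abcd"), m, np.ones((4, 4), int)))
        assert bipartitions(tree) == {frozenset({"c", "d"})}
        lengths = {t.name: t.branch_length for t in tree.get_terminals()}
        assert lengths == pytest.approx({"a": 1, "b": 2, "c": 3, "d": 4})

    def test_ultrametric_matches_upgma_grouping(self):
        m = np.array(
            [
                [0, 0.2, 0.6, 0.6],
                [0.2, 0, 0.6, 0.6],
                [0.6, 0.6, 0, 0.3],
                [0.6, 0.6, 0.3, 0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(list("abcd"), m, np.ones((4, 4), int)))
        assert bipartitions(tree) == {frozenset({"c", "d"})}

    @pytest.mark.parametrize("n_taxa", [5, 6, 8])
    def test_additive_recovery_random_trees(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        for _ in range(10):
            labels, dist, true_splits = build_additive(n_taxa, rng)
            dm = DistanceMatrix(labels, dist, np.ones_like(dist, dtype=int))
            tree = neighbor_joining(dm)
            assert bipartitions(tree) == true_splits
            # path lengths on the reconstructed tree reproduce the matrix
            terminals = {t.name: t for t in tree.get_terminals()}
            for i, a in enumerate(labels):
                for j in range(i + 1, len(labels)):
                    d = tree.distance(terminals[a], terminals[labels[j]])
                    assert d == pytest.approx(dist[i, j], abs=1e-9)

    def test_matches_reference_nj_implementation(self):
        """Topology agrees with scikit-bio's NJ on generic random matrices."""
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(42)
        for _ in range(5):
            n = 6
            a = rng.uniform(0.1, 1.0, size=(n, n))
            m = (a + a.T) / 2
            np.fill_diagonal(m, 0)
            labels = [f"t{i:02d}" for i in range(n)]
            mine = neighbor_joining(DistanceMatrix(labels, m, np.ones_like(m, dtype=int)))
            ref = sk_nj(skbio.DistanceMatrix(m, ids=labels))
            ref_splits = set()
            all_set = set(labels)
            for node in ref.non_tips(include_self=False):
                side = {t.name for t in node.tips()}
                if 2 <= len(side) <= n - 2:
                    if min(labels) in side:
                        side = all_set - side
                    ref_splits.add(frozenset(side))
            assert bipartitions(mine) == ref_splits


class TestBootstrap:
    @staticmethod
    def clean_alignment():
        a = "A" * 30 + "C" * 30
        b = "A" * 30 + "C" * 28 + "GG"
        c = "T" * 30 + "G" * 30
        d = "T" * 30 + "G" * 28 + "AA"
        return [("a", a), ("b", b), ("c", c), ("d", d)]

    def test_identical_clades_full_support(self):
        tree = bootstrap_support(self.clean_alignment(), n_boot=100, seed=1)
        internal = [c for c in tree.get_nonterminals() if c.confidence is not None]
        assert internal
        assert all(c.confidence == 100 for c in internal)

    def test_no_bootstrap_requested(self):
        tree = bootstrap_support(self.clean_alignment(), n_boot=0, seed=1)
        assert all(c.confidence is None for c in tree.get_nonterminals())

    def test_strong_split_high_support(self):
        """50 fixed differences across the split give >= 95% support."""
        rng = np.random.default_rng(9)
        bases = "ACGT"
        core = "".join(rng.choice(list(bases), 150))
        left = core[:50] + "A" * 50 + core[100:]
        right = core[:50] + "T" * 50 + core[100:]

        def mutate(seq, n, seed):
            r = np.random.default_rng(seed)
            s = list(seq)
            for pos in r.choice(len(s), size=n, replace=False):
                s[pos] = bases[(bases.index(s[pos]) + 1) % 4]
            return "".join(s)

        aln = [
            ("l1", mutate(left, 3, 1)),
            ("l2", mutate(left, 3, 2)),
            ("r1", mutate(right, 3, 3)),
            ("r2", mutate(right, 3, 4)),
        ]
        tree = bootstrap_support(aln, n_boot=200, seed=5)
        supports = [c.confidence for c in tree.get_nonterminals() if c.confidence is not None]
        assert supports and max(supports) >= 95
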