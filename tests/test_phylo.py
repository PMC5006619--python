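"""Neighbor joining, p-distances, bootstrap: exact small-scale checks."""
import numpy as np
import pytest

from retrotarget.phylo import (
    DistanceMatrix, bipartitions, bootstrap, midpoint_root, neighbor_joining,
    pdistance, root_on,
)


# ---------------------------------------------------------------------------
# oracles

def _enumerate_quartet_fit(d):
    """Least-squares branch fit for each of the 3 unrooted quartets.

    Returns the split (frozenset pair) of the zero-residual topology.
    For quartet {0,1,2,3} and split (01|23): path matrix over branches
    [e0,e1,e2,e3,internal].
    """
    best = None
    for pair in [(0, 1), (0, 2), (0, 3)]:
        a, b = pair
        c, e = [x for x in range(4) if x not in pair]
        rows = []
        y = []
        def path(i, j):
            v = [0] * 5
            v[i] = v[j] = 1
            same = {i, j} in ({a, b}, {c, e})
            if not same:
                v[4] = 1
            return v
        for i in range(4):
            for j in range(i + 1, 4):
                rows.append(path(i, j))
                y.append(d[i, j])
        A = np.array(rows, float)
        x, res, *_ = np.linalg.lstsq(A, np.array(y), rcond=None)
        resid = np.linalg.norm(A @ x - y)
        if best is None or resid < best[0]:
            best = (resid, frozenset([a, b]), x)
    return best


# ---------------------------------------------------------------------------

class TestPdistance:
    def test_quarter_difference(self):
        D = pdistance([("a", "AAAA"), ("b", "AAAT"), ("c", "AATT")])
        assert D.d[0, 1] == 0.25
        assert D.d[0, 2] == 0.5

    def test_complete_deletion_removes_gap_columns(self):
        D = pdistance([("a", "A-CG"), ("b", "ATCG"), ("c", "AACG")])
        assert D.n_sites_used == 3
        assert D.d[0, 1] == 0.0

    def test_identical_sequences_zero(self):
        D = pdistance([("a", "KLMN"), ("b", "KLMN"), ("c", "KLMN")])
        assert np.all(D.d == 0)

    def test_all_gap_column_never_changes_distances(self):
        rows = [("a", "KRMNQ"), ("b", "KLMNE"), ("c", "KLMWQ")]
        rows2 = [(n, s[:2] + "-" + s[2:]) for n, s in rows]
        rows2 = [(n, s) for n, s in rows2]
        base = pdistance(rows)
        aug = pdistance([(n, s[:2] + "-" + s[2:]) for n, s in rows])
        assert np.allclose(base.d, aug.d)

    def test_no_retained_columns_rejected(self):
        with pytest.raises(ValueError):
            pdistance([("a", "K-"), ("b", "-L"), ("c", "XX")])

    def test_x_treated_as_missing(self):
        D = pdistance([("a", "KXMN"), ("b", "KLMN"), ("c", "KRMN")])
        assert D.n_sites_used == 3


class TestNeighborJoining:
    def test_quartet_exact_recovery_vs_least_squares(self):
        """NJ matches the zero-residual least-squares quartet."""
        # tree (A:1,B:2):1,(C:3,D:4) -> additive distances
        taxa = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        resid, split, branches = _enumerate_quartet_fit(d)
        assert resid < 1e-9 and split == frozenset([0, 1])
        tree = neighbor_joining(DistanceMatrix(taxa, d, 0))
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        # exact branch lengths
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d, 0))
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_random_additive_trees_recovered(self):
        """For additive matrices on 5-6 taxa NJ recovers the generating
        topology (cross-checked against scikit-bio's implementation)."""
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj
        import networkx as nx
        rng = np.random.default_rng(99)
        for n in (5, 6):
            for _ in range(10):
                # random binary tree over n leaves via networkx edges
                g = nx.Graph()
                nodes = list(range(n))
                nxt = n
                while len(nodes) > 1:
                    i = nodes.pop(int(rng.integers(len(nodes))))
                    j = nodes.pop(int(rng.integers(len(nodes))))
                    g.add_edge(i, nxt, weight=float(rng.integers(1, 9)))
                    g.add_edge(j, nxt, weight=float(rng.integers(1, 9)))
                    nodes.append(nxt)
                    nxt += 1
                d = np.zeros((n, n))
                for i in range(n):
                    lens = nx.single_source_dijkstra_path_length(g, i)
                    for j in range(n):
                        d[i, j] = lens[j]
                taxa = [f"T{i}" for i in range(n)]
                tree = neighbor_joining(DistanceMatrix(taxa, d, 0))
                # truth splits from the generating tree
                true_splits = set()
                for a, b in g.edges:
                    g2 = g.copy()
                    g2.remove_edge(a, b)
                    side = {x for x in nx.node_connected_component(g2, a)
                            if x < n}
                    if 1 < len(side) < n - 1:
                        ref_side = (side if 0 not in side
                                    else {x for x in range(n)} - side)
                        true_splits.add(frozenset(f"T{i}" for i in ref_side))
                assert bipartitions(tree) == true_splits
                sk = sk_nj(SkDM(d, ids=taxa))
                sk_splits = set()
                for node in sk.non_tips():
                    below = {t.name for t in node.tips()}
                    if 1 < len(below) < n - 1:
                        side = (below if "T0" not in below
                                else {f"T{i}" for i in range(n)} - below)
                        sk_splits.add(frozenset(side))
                assert sk_splits == true_splits

    def test_taxon_order_permutation_invariant(self):
        rng = np.random.default_rng(3)
        taxa = ["A", "B", "C", "D", "E"]
        d = np.array([[0, 2, 7, 7, 8], [2, 0, 7, 7, 8], [7, 7, 0, 2, 9],
                      [7, 7, 2, 0, 9], [8, 8, 9, 9, 0]], float)
        base = bipartitions(neighbor_joining(DistanceMatrix(taxa, d, 0)))
        for _ in range(5):
            perm = rng.permutation(5)
            t2 = [taxa[i] for i in perm]
            d2 = d[np.ix_(perm, perm)]
            assert bipartitions(neighbor_joining(DistanceMatrix(t2, d2, 0))) == base

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"], d, 0)

    def test_negative_branches_clamped(self):
        d = np.array([[0, 0.1, 0.9, 0.9], [0.1, 0, 0.9, 0.9],
                      [0.9, 0.9, 0, 0.05], [0.9, 0.9, 0.05, 0]])
        tree = neighbor_joining(DistanceMatrix(list("abcd"), d, 0))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0


class TestBootstrap:
    UNAMBIG = [("A", "KKKKKKKK"), ("B", "KKKKKKKK"),
               ("C", "DDDDDDDD"), ("D", "DDDDDDDD")]

    def test_unambiguous_alignment_full_support(self):
        tree = bootstrap(self.UNAMBIG, n_reps=200, seed=1)
        labels = [nd.label for nd in tree.preorder_node_iter() if nd.label]
        assert labels == ["100"]

    def test_supports_within_range_and_deterministic(self):
        rng = np.random.default_rng(0)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        rows = [(f"s{i}", "".join(aa[j] for j in rng.integers(0, 20, 60)))
                for i in range(5)]
        t1 = bootstrap(rows, n_reps=100, seed=7)
        t2 = bootstrap(rows, n_reps=100, seed=7)
        s1 = [nd.label for nd in t1.preorder_node_iter() if nd.label]
        assert all(0 <= int(s) <= 100 for s in s1)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_nonpositive_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap(self.UNAMBIG, n_reps=0)


class TestRooting:
    @pytest.fixture()
    def quartet(self):
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        return neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], d, 0))

    def test_single_outgroup_bisects_pendant_edge(self, quartet):
        rooted = root_on(quartet, ["D"])
        kids = rooted.seed_node.child_nodes()
        d_child = next(k for k in kids if k.is_leaf() and k.taxon.label == "D")
        assert d_child.edge.length == pytest.approx(2.0)

    def test_rooting_preserves_bipartitions(self, quartet):
        before = bipartitions(quartet)
        rooted = root_on(quartet, ["C", "D"])
        # compare unrooted splits after collapsing the root edge
        after = set()
        labels = {l.taxon.label for l in rooted.leaf_node_iter()}
        for nd in rooted.preorder_node_iter():
            if nd is rooted.seed_node or nd.is_leaf():
                continue
            below = {l.taxon.label for l in nd.leaf_iter()}
            if 1 < len(below) < len(labels) - 1:
                side = below if "A" not in below else labels - below
                after.add(frozenset(side))
        assert before <= after or before == after

    def test_midpoint_root(self, quartet):
        rooted = midpoint_root(quartet)
        depths = {l.taxon.label: l.distance_from_root()
                  for l in rooted.leaf_node_iter()}
        # longest path B..D has length 7 -> deepest leaves sit at 3.5
        assert max(depths.values()) == pytest.approx(3.5)

    def test_missing_outgroup_rejected(self, quartet):
        with pytest.raises(ValueError, match="outgroup"):
            root_on(quartet, ["Z"])
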