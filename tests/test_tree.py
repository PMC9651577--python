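"""Neighbor-Joining construction, bootstrap, rooting and Newick round-trips."""

import numpy as np
import pytest

from conftest import path_length_matrix, random_binary_tree
from fawclans.distances import DistanceMatrix, pairwise_distance
from fawclans.io import AlignedSequenceSet
from fawclans.njtree import (NewickParseError, bipartitions, bootstrap_support,
                             midpoint_root, nj_tree, outgroup_root,
                             read_newick, tree_length, write_newick)


def dm_from(labels, m):
    return DistanceMatrix(labels=tuple(labels), d=np.asarray(m, dtype=float),
                          model="p", deletion="complete")


def patristic(tree):
    """Leaf-to-leaf path length dict keyed by frozenset of two labels."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1 in pdm.taxon_iter():
        for t2 in pdm.taxon_iter():
            if t1 is not t2:
                out[frozenset((t1.label, t2.label))] = pdm.distance(t1, t2)
    return out


ADDITIVE4 = dm_from("ABCD", [[0, 2, 4, 4],
                             [2, 0, 4, 4],
                             [4, 4, 0, 2],
                             [4, 4, 2, 0]])


class TestNeighborJoining:
    def test_additive_four_taxon_topology_and_lengths(self):
        tree = nj_tree(ADDITIVE4)
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        p = patristic(tree)
        assert p[frozenset(("A", "B"))] == pytest.approx(2.0, abs=1e-9)
        assert p[frozenset(("C", "D"))] == pytest.approx(2.0, abs=1e-9)
        assert p[frozenset(("A", "C"))] == pytest.approx(4.0, abs=1e-9)
        # cherry branches 1 each -> internal edge must be 2
        assert tree_length(tree) == pytest.approx(6.0, abs=1e-9)

    def test_three_taxa_three_point_formula(self):
        dm = dm_from("ABC", [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        tree = nj_tree(dm)
        p = patristic(tree)
        # la = (3+4-5)/2 = 1, lb = (3+5-4)/2 = 2, lc = (4+5-3)/2 = 3
        assert p[frozenset(("A", "B"))] == pytest.approx(3.0, abs=1e-9)
        assert p[frozenset(("A", "C"))] == pytest.approx(4.0, abs=1e-9)
        assert p[frozenset(("B", "C"))] == pytest.approx(5.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_recovers_random_additive_topology(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        children, lengths, root = random_binary_tree(n, rng)
        m = path_length_matrix(children, lengths, root, n)
        labels = [f"t{i}" for i in range(n)]
        tree = nj_tree(dm_from(labels, m))
        # NJ is consistent on additive matrices: path lengths match input
        p = patristic(tree)
        for i in range(n):
            for j in range(i + 1, n):
                assert p[frozenset((f"t{i}", f"t{j}"))] == \
                    pytest.approx(m[i, j], abs=1e-9)

    def test_matches_independent_nj_implementation(self):
        # cross-check topology against scikit-bio's neighbor joining
        import skbio

        rng = np.random.default_rng(7)
        n = 10
        children, lengths, root = random_binary_tree(n, rng)
        m = path_length_matrix(children, lengths, root, n)
        labels = [f"t{i}" for i in range(n)]
        ours = nj_tree(dm_from(labels, m))
        sk = skbio.tree.nj(skbio.DistanceMatrix(m, ids=labels))
        sk_splits = set()
        all_labels = frozenset(labels)
        ref = min(all_labels)
        for node in sk.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = all_labels - side
            if 1 < len(side) < n - 1:
                sk_splits.add(side)
        assert bipartitions(ours) == sk_splits

    def test_too_few_labels(self):
        with pytest.raises(ValueError):
            nj_tree(dm_from("AB", [[0, 1], [1, 0]]))


class TestBootstrap:
    def _two_clades(self):
        # 20 fixed differences between clades, none within
        left = "A" * 20 + "C" * 30
        right = "G" * 20 + "C" * 30
        return AlignedSequenceSet({
            "l1": left, "l2": left, "l3": left,
            "r1": right, "r2": right, "r3": right,
        })

    def test_clean_split_gets_full_support(self):
        # every column resample keeps >=1 of the 20 fixed differences, so the
        # between-clade bipartition must appear in every replicate
        tree = bootstrap_support(self._two_clades(), model="p", n_reps=20,
                                 seed=1)
        all_labels = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        ref = min(all_labels)
        split_support = None
        for nd in tree.preorder_node_iter():
            if nd.is_leaf() or nd.label is None:
                continue
            side = frozenset(l.taxon.label for l in nd.leaf_iter())
            if ref in side:
                side = all_labels - side
            if side in (frozenset({"l1", "l2", "l3"}),
                        frozenset({"r1", "r2", "r3"})):
                split_support = int(nd.label)
        assert split_support == 100

    def test_single_replicate_supports_binary(self):
        tree = bootstrap_support(self._two_clades(), model="p", n_reps=1,
                                 seed=5)
        supports = [int(nd.label) for nd in tree.preorder_node_iter()
                    if nd.label is not None and not nd.is_leaf()]
        assert set(supports) <= {0, 100}

    def test_fixed_seed_is_deterministic(self):
        rng = np.random.default_rng(3)
        records = {
            f"s{i}": "".join(rng.choice(list("ACGT"), size=60))
            for i in range(6)
        }
        seqs = AlignedSequenceSet(records)
        t1 = bootstrap_support(seqs, model="p", n_reps=30, seed=42)
        t2 = bootstrap_support(seqs, model="p", n_reps=30, seed=42)
        assert write_newick(t1) == write_newick(t2)

    def test_supports_invariant_to_leaf_order(self):
        seqs = self._two_clades()
        shuffled = AlignedSequenceSet(
            {k: seqs.records[k] for k in reversed(seqs.ids)})
        t1 = bootstrap_support(seqs, model="p", n_reps=25, seed=9)
        t2 = bootstrap_support(shuffled, model="p", n_reps=25, seed=9)

        def support_map(t):
            out = {}
            all_labels = frozenset(l.taxon.label for l in t.leaf_node_iter())
            ref = min(all_labels)
            for nd in t.preorder_node_iter():
                if nd.is_leaf() or nd.label is None:
                    continue
                side = frozenset(l.taxon.label for l in nd.leaf_iter())
                if ref in side:
                    side = all_labels - side
                out[side] = int(nd.label)
            return out

        assert support_map(t1) == support_map(t2)


class TestRooting:
    def test_midpoint_on_chain(self):
        # A --3-- B: midpoint is 1.5 from each
        tree = read_newick("(A:1.0,B:2.0);")
        rooted = midpoint_root(tree)
        dists = {lf.taxon.label: lf.distance_from_root()
                 for lf in rooted.leaf_node_iter()}
        assert dists["A"] == pytest.approx(1.5)
        assert dists["B"] == pytest.approx(1.5)

    def test_midpoint_preserves_topology_and_length(self):
        tree = nj_tree(ADDITIVE4)
        rooted = midpoint_root(tree)
        assert bipartitions(rooted) == bipartitions(tree)
        assert tree_length(rooted) == pytest.approx(tree_length(tree),
                                                    abs=1e-9)

    def test_outgroup_root_bipartition(self):
        tree = nj_tree(ADDITIVE4)
        rooted = outgroup_root(tree, ["A"])
        kids = rooted.seed_node.child_nodes()
        sides = [frozenset(l.taxon.label for l in k.leaf_iter()) for k in kids]
        assert frozenset({"A"}) in sides
        assert frozenset({"B", "C", "D"}) in sides

    def test_outgroup_pair(self):
        tree = nj_tree(ADDITIVE4)
        rooted = outgroup_root(tree, ["C", "D"])
        sides = [frozenset(l.taxon.label for l in k.leaf_iter())
                 for k in rooted.seed_node.child_nodes()]
        assert frozenset({"C", "D"}) in sides

    def test_non_monophyletic_outgroup_rejected(self):
        tree = nj_tree(ADDITIVE4)
        with pytest.raises(ValueError, match="monophyletic"):
            outgroup_root(tree, ["A", "C"])

    def test_missing_outgroup_id(self):
        tree = nj_tree(ADDITIVE4)
        with pytest.raises(ValueError, match="absent"):
            outgroup_root(tree, ["Z"])


class TestNewickRoundTrip:
    def test_small_tree_round_trip(self):
        tree = nj_tree(ADDITIVE4)
        text = write_newick(tree)
        back = read_newick(text)
        assert bipartitions(back) == bipartitions(tree)
        p1, p2 = patristic(tree), patristic(back)
        for key in p1:
            assert p2[key] == pytest.approx(p1[key], abs=1e-9)

    def test_fifty_leaf_round_trip(self):
        rng = np.random.default_rng(11)
        n = 50
        children, lengths, root = random_binary_tree(n, rng)
        m = path_length_matrix(children, lengths, root, n)
        tree = nj_tree(dm_from([f"t{i}" for i in range(n)], m))
        back = read_newick(write_newick(tree))
        assert bipartitions(back) == bipartitions(tree)

    def test_supports_survive_round_trip(self):
        text = "((A:1,B:1)95:2,(C:1,D:1)80:2);"
        tree = read_newick(text)
        labels = sorted(nd.label for nd in tree.preorder_node_iter()
                        if not nd.is_leaf() and nd.label)
        assert labels == ["80", "95"]

    @pytest.mark.parametrize("bad", ["", "   ", "((A,B);", "(A:1,B:oops);"])
    def test_malformed_newick(self, bad):
        with pytest.raises(NewickParseError):
            read_newick(bad)
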