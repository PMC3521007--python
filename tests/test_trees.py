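"""Tree model: Newick round trips, bipartitions, rooting."""

import math

import numpy as np
import pytest

from hgtscan.trees import (
    Bipartition,
    NewickError,
    Tree,
    TreeNode,
    bipartitions,
    leaf_path_lengths,
    midpoint_root,
    outgroup_root,
    pairwise_leaf_distances,
    parse_newick,
    root_by_split,
    tree_from_bipartitions,
    write_newick,
)

from conftest import random_tree


class TestParse:
    def test_minimal_two_leaf(self):
        t = parse_newick("(A:1,B:2);")
        assert sorted(t.leaf_labels()) == ["A", "B"]
        assert {lf.label: lf.length for lf in t.leaves()} == {"A": 1.0, "B": 2.0}

    def test_four_leaf_structure(self):
        t = parse_newick("((A,B),(C,D));")
        assert len(t) == 4
        assert all(len(c.children) == 2 for c in t.root.children)

    @pytest.mark.parametrize(
        "text",
        ["(A,B", "(A,,B);", "(A:x,B:1);", "", "(A,B));"],
    )
    def test_malformed_rejected(self, text):
        with pytest.raises((NewickError, ValueError)):
            parse_newick(text)

    def test_error_names_position(self):
        with pytest.raises(NewickError, match="position"):
            parse_newick("(A,(B,C)")

    def test_duplicate_leaf_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_newick("(A,(A,B));")

    def test_quoted_labels_comments_scientific_lengths(self):
        t = parse_newick("('sp. one':1e-2,[note]'B''s':2.5E1);")
        assert sorted(t.leaf_labels()) == ["B's", "sp. one"]
        lengths = {lf.label: lf.length for lf in t.leaves()}
        assert lengths["sp. one"] == pytest.approx(0.01)
        assert lengths["B's"] == pytest.approx(25.0)


class TestWrite:
    def test_round_trip_small(self):
        text = "(A:1,B:2);"
        assert write_newick(parse_newick(text)) in ("(A:1,B:2);", "(B:2,A:1);")

    def test_empty_tree_rejected(self):
        with pytest.raises(ValueError):
            Tree(None)  # no root at all
        with pytest.raises(ValueError):
            Tree(TreeNode())  # a single unlabeled leaf

    def test_support_triplet_survives_round_trip(self):
        t = parse_newick("((A,B)97/82/64:0.1,(C,D));")
        inner = [n for n in t.postorder() if n.children and n is not t.root][0]
        assert inner.supports == [("ML", 97.0), ("NJ", 82.0), ("MP", 64.0)]
        t2 = parse_newick(write_newick(t))
        inner2 = [n for n in t2.postorder() if n.children and n is not t2.root][0]
        assert inner2.supports == inner.supports

    def test_missing_method_serialized_as_dash(self):
        t = parse_newick("((A,B)-/82/64,(C,D));")
        inner = [n for n in t.postorder() if n.children and n is not t.root][0]
        assert inner.supports[0] == ("ML", None)
        assert "-/82/64" in write_newick(t)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tree_round_trip(self, seed):
        """Topology, labels and lengths survive write→parse on 50-leaf trees."""
        rng = np.random.default_rng(seed)
        labels = [f"t{i:02d}" for i in range(50)]
        t = random_tree(labels, rng)
        t2 = parse_newick(write_newick(t))
        assert bipartitions(t) == bipartitions(t2)
        d1, d2 = leaf_path_lengths(t), leaf_path_lengths(t2)
        assert d1.keys() == d2.keys()
        assert all(math.isclose(d1[k], d2[k], abs_tol=1e-9) for k in d1)

    def test_dendropy_agrees_on_round_trip(self):
        """Cross-check the writer against an independent Newick reader."""
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(7)
        t = random_tree([f"t{i}" for i in range(20)], rng)
        dt = dendropy.Tree.get(data=write_newick(t), schema="newick")
        labels = set(t.leaf_labels())
        assert {lf.taxon.label for lf in dt.leaf_node_iter()} == labels
        their = set()
        for node in dt.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            block = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 1 < len(block) < len(labels) - 1:
                their.add(Bipartition(block, labels))
        assert their == bipartitions(t)


class TestBipartitions:
    def test_quartet(self):
        t = parse_newick("((A,B),(C,D));")
        bps = bipartitions(t)
        assert bps == {Bipartition({"C", "D"}, "ABCD")}

    def test_star_has_none(self):
        assert bipartitions(parse_newick("(A,B,C,D);")) == set()

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_caterpillar_count(self, n):
        text = "A0"
        for i in range(1, n):
            text = f"({text},A{i})"
        t = parse_newick(text + ";")
        assert len(bipartitions(t)) == n - 3

    @pytest.mark.parametrize("seed", range(10))
    def test_invariant_under_rerooting(self, seed):
        rng = np.random.default_rng(seed)
        t = random_tree([f"x{i}" for i in range(12)], rng)
        other = midpoint_root(t)
        assert bipartitions(t) == bipartitions(other)

    def test_tree_from_bipartitions_inverts(self):
        rng = np.random.default_rng(3)
        t = random_tree([f"x{i}" for i in range(15)], rng)
        rebuilt = tree_from_bipartitions(t.leaf_labels(), bipartitions(t))
        assert bipartitions(rebuilt) == bipartitions(t)


class TestMidpointRoot:
    def test_two_leaf_midpoint(self):
        t = midpoint_root(parse_newick("(A:1,B:3);"))
        depths = leaf_path_lengths(t)
        assert depths == pytest.approx({"A": 2.0, "B": 2.0})

    def test_symmetric_tree_root_on_central_edge(self):
        t = midpoint_root(parse_newick("((A:1,B:1):2,(C:1,D:1):2);"))
        depths = leaf_path_lengths(t)
        assert all(d == pytest.approx(3.0) for d in depths.values())

    def test_missing_lengths_error(self):
        with pytest.raises(ValueError):
            midpoint_root(parse_newick("((A,B),(C,D));"))

    @pytest.mark.parametrize("seed", range(8))
    def test_idempotent_and_distance_preserving(self, seed):
        rng = np.random.default_rng(seed)
        t = random_tree([f"x{i}" for i in range(10)], rng)
        m1 = midpoint_root(t)
        m2 = midpoint_root(m1)
        d0, d1, d2 = (pairwise_leaf_distances(x) for x in (t, m1, m2))
        for k in d0:
            assert math.isclose(d0[k], d1[k], abs_tol=1e-9)
            assert math.isclose(d1[k], d2[k], abs_tol=1e-9)
        # root depths identical between successive applications
        p1, p2 = leaf_path_lengths(m1), leaf_path_lengths(m2)
        assert all(math.isclose(p1[k], p2[k], abs_tol=1e-9) for k in p1)


class TestOutgroupRoot:
    def test_roots_above_outgroup_clade(self):
        t = parse_newick("(((A:1,B:1):1,C:1):1,(O1:1,O2:1):1);")
        rooted = outgroup_root(t, ["O1", "O2"])
        sides = [sorted(lf.label for lf in c.leaves()) for c in rooted.root.children]
        assert ["O1", "O2"] in sides

    def test_missing_outgroup_taxon_errors(self):
        t = parse_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError, match="not in tree"):
            outgroup_root(t, ["Z"])


class TestRootBySplit:
    def test_recovers_reference_split(self):
        t = parse_newick("((A,B),((C,D),(E,F)));")
        rooted = root_by_split(t, {"A", "B"})
        sides = [frozenset(lf.label for lf in c.leaves()) for c in rooted.root.children]
        assert frozenset({"A", "B"}) in sides
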