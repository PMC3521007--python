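"""Foreign-leaf screening: wrap test, host regions, length filter."""

import pytest

from hgtscan.screen import (
    HGTCandidate,
    ScreenParams,
    detect_foreign_leaves,
    extract_kingdom_subtrees,
    filter_by_length,
    populate_fragment_lengths,
)
from hgtscan.simulate import SimParams, plant_hgt_events, simulate_labeled_tree
from hgtscan.trees import parse_newick

B, P, A = "Bacteria", "Plantae", "Archaea"

FIVE = {"b1": B, "b2": B, "b3": B, "b4": B, "p1": P}


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            ScreenParams(min_fragment_length=0)
        with pytest.raises(ValueError):
            ScreenParams(purity=0.0)
        with pytest.raises(ValueError):
            ScreenParams(purity=1.2)
        with pytest.raises(ValueError):
            ScreenParams(min_native=0)

    def test_candidate_invariants(self):
        with pytest.raises(ValueError):
            HGTCandidate("x", B, B, 3, 1.0)
        with pytest.raises(ValueError):
            HGTCandidate("x", B, P, 3, 1.5)


class TestExtractSubtrees:
    def test_monophyletic_kingdoms_one_subtree_each(self):
        t = parse_newick("((b1,(b2,b3)),(p1,(p2,p3)));")
        kmap = {"b1": B, "b2": B, "b3": B, "p1": P, "p2": P, "p3": P}
        subs = extract_kingdom_subtrees(t, kmap, B, ScreenParams())
        assert [sorted(s.leaf_labels()) for s in subs] == [["b1", "b2", "b3"]]

    def test_purity_below_one_takes_maximal_clade(self):
        t = parse_newick("((b1,b2),((b3,b4),p1));")
        subs = extract_kingdom_subtrees(
            t, FIVE, B, ScreenParams(min_native=3, purity=0.75)
        )
        assert [sorted(s.leaf_labels()) for s in subs] == [
            ["b1", "b2", "b3", "b4", "p1"]
        ]

    def test_strict_purity_leaves_only_small_pure_clades(self):
        subs = extract_kingdom_subtrees(
            parse_newick("((b1,b2),((b3,b4),p1));"),
            FIVE,
            B,
            ScreenParams(min_native=3, purity=1.0),
        )
        assert subs == []

    def test_absent_kingdom_warns_empty(self):
        t = parse_newick("((b1,b2),(b3,b4));")
        subs = extract_kingdom_subtrees(
            t, {k: B for k in "b1 b2 b3 b4".split()}, A, ScreenParams()
        )
        assert subs == []


class TestDetect:
    def test_single_nested_leaf(self):
        t = parse_newick("((b1,b2),((b3,b4),p1));")
        cands = detect_foreign_leaves(t, FIVE, ScreenParams(min_native=2))
        assert [(c.leaf_id, c.native_kingdom, c.host_kingdom) for c in cands] == [
            ("p1", P, B)
        ]
        assert cands[0].host_clade_size == 3
        assert cands[0].purity == 1.0

    def test_min_native_three_suppresses_small_host(self):
        t = parse_newick("((b1,b2),((b3,b4),p1));")
        assert detect_foreign_leaves(t, FIVE, ScreenParams(min_native=3)) == []

    def test_monophyletic_kingdoms_no_candidates(self):
        t = parse_newick("(((b1,(b2,b3)),(p1,(p2,p3))),(a1,(a2,a3)));")
        kmap = {f"b{i}": B for i in range(1, 4)}
        kmap |= {f"p{i}": P for i in range(1, 4)}
        kmap |= {f"a{i}": A for i in range(1, 4)}
        assert detect_foreign_leaves(t, kmap, ScreenParams(min_native=2)) == []

    def test_foreign_cherry_reported_together(self):
        t = parse_newick("((b1,b2),((b3,(p1,p2)),(b4,b5)));")
        kmap = {f"b{i}": B for i in range(1, 6)} | {"p1": P, "p2": P}
        cands = detect_foreign_leaves(t, kmap, ScreenParams(min_native=2))
        assert [(c.leaf_id, c.host_clade_size) for c in cands] == [
            ("p1", 5),
            ("p2", 5),
        ]

    def test_unknown_leaves_cannot_be_candidates(self):
        t = parse_newick("((b1,b2),((b3,b4),(p1,u1)));")
        kmap = dict(FIVE)  # u1 absent → Unknown
        cands = detect_foreign_leaves(t, kmap, ScreenParams(min_native=2))
        assert {c.leaf_id for c in cands} == {"p1"}

    def test_kingdom_restriction(self):
        t = parse_newick("(((b1,b2),((b3,b4),p1)),((p2,p3),((p4,p5),b5)));")
        kmap = {f"b{i}": B for i in range(1, 6)}
        kmap |= {f"p{i}": P for i in range(1, 6)}
        both = detect_foreign_leaves(t, kmap, ScreenParams(min_native=2))
        assert {c.leaf_id for c in both} == {"p1", "b5"}
        only_b = detect_foreign_leaves(
            t, kmap, ScreenParams(min_native=2, kingdom=B)
        )
        assert {c.leaf_id for c in only_b} == {"p1"}

    def test_unrooted_tree_without_lengths_or_outgroup_errors(self):
        t = parse_newick("(b1,b2,(b3,(b4,p1)));")
        assert not t.is_rooted
        with pytest.raises(ValueError, match="root"):
            detect_foreign_leaves(t, FIVE, ScreenParams(min_native=2))

    def test_outgroup_rooting_used_when_configured(self):
        t = parse_newick("(b1,b2,((b3,(b4,p1)),(o1,o2)));")
        kmap = dict(FIVE) | {"o1": A, "o2": A}
        cands = detect_foreign_leaves(
            t, kmap, ScreenParams(min_native=2, outgroup=("o1", "o2"))
        )
        assert {c.leaf_id for c in cands} == {"p1"}

    @pytest.mark.parametrize("seed", range(30))
    def test_planted_transfers_recovered_exactly(self, seed):
        """Noise-free screening equals the planted truth (recall and precision 1)."""
        params = SimParams(seed=seed)
        tree, kmap, _ = simulate_labeled_tree(params)
        planted, truth = plant_hgt_events(tree, kmap, params)
        called = {
            c.leaf_id for c in detect_foreign_leaves(planted, kmap, ScreenParams())
        }
        assert called == truth.transferred_leaves

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_thresholds(self, seed):
        params = SimParams(seed=seed)
        tree, kmap, _ = simulate_labeled_tree(params)
        planted, _ = plant_hgt_events(tree, kmap, params)
        counts = [
            len(detect_foreign_leaves(planted, kmap, ScreenParams(min_native=m)))
            for m in (2, 3, 5, 8)
        ]
        assert counts == sorted(counts, reverse=True)
        by_purity = [
            len(detect_foreign_leaves(planted, kmap, ScreenParams(purity=p)))
            for p in (0.6, 0.8, 1.0)
        ]
        assert by_purity == sorted(by_purity, reverse=True)


class TestLengthFilter:
    def c(self, length):
        return HGTCandidate("x", P, B, 4, 1.0, fragment_length=length)

    def test_boundary_just_below_removed(self):
        assert filter_by_length([self.c(299)], ScreenParams()) == []

    def test_boundary_exact_retained(self):
        assert len(filter_by_length([self.c(300)], ScreenParams())) == 1

    def test_empty_input(self):
        assert filter_by_length([], ScreenParams()) == []

    def test_missing_length_retained_flagged(self):
        (kept,) = filter_by_length([self.c(None)], ScreenParams())
        assert kept.note == "length-missing"

    def test_populate_prefers_aligned_lengths(self):
        cands = populate_fragment_lengths(
            [self.c(None)], aligned_lengths={"x": 310}, full_lengths={"x": 500}
        )
        assert cands[0].fragment_length == 310
        cands = populate_fragment_lengths([self.c(None)], full_lengths={"x": 500})
        assert cands[0].fragment_length == 500
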