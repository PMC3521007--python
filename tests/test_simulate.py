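"""Synthetic gene families: planted transfers, sequence evolution, ensembles."""

import math

import numpy as np
import pytest

from hgtscan.alignment import mos_scores
from hgtscan.infer import poisson_distance
from hgtscan.screen import ScreenParams, detect_foreign_leaves
from hgtscan.simulate import (
    PlantedEvent,
    SimParams,
    SyntheticTruth,
    evaluate_recovery,
    evolve_sequences,
    perturb_alignment,
    plant_hgt_events,
    simulate_labeled_tree,
    true_alignment,
)
from hgtscan.trees import parse_newick, write_newick


class TestSimulateTree:
    def test_two_kingdoms_five_each(self):
        p = SimParams(leaves_per_kingdom=5, n_events=0, seed=1)
        tree, kmap, records = simulate_labeled_tree(p)
        assert len(tree) == 10
        assert all(len(n.children) == 2 for n in tree.postorder() if n.children)
        # each kingdom monophyletic
        for kingdom in p.kingdoms:
            members = {lf for lf, k in kmap.items() if k == kingdom}
            clades = {
                frozenset(lf.label for lf in n.leaves()) for n in tree.postorder()
            }
            assert frozenset(members) in clades
        assert {r.id for r in records} == set(kmap)

    def test_deterministic_per_seed(self):
        p = SimParams(seed=7)
        t1, _, _ = simulate_labeled_tree(p)
        t2, _, _ = simulate_labeled_tree(p)
        assert write_newick(t1) == write_newick(t2)
        t3, _, _ = simulate_labeled_tree(SimParams(seed=8))
        assert write_newick(t3) != write_newick(t1)

    def test_no_hgt_control_screens_clean(self):
        p = SimParams(seed=3)
        tree, kmap, _ = simulate_labeled_tree(p)
        assert detect_foreign_leaves(tree, kmap, ScreenParams(min_native=1)) == []

    def test_infeasible_counts_error(self):
        with pytest.raises(ValueError):
            simulate_labeled_tree(SimParams(leaves_per_kingdom=1, seed=0))


class TestPlantEvents:
    def test_zero_events_unchanged(self):
        p = SimParams(n_events=0, seed=2)
        tree, kmap, _ = simulate_labeled_tree(p)
        planted, truth = plant_hgt_events(tree, kmap, p)
        assert truth.events == []
        assert write_newick_topology(planted) == write_newick_topology(tree)

    def test_truth_bookkeeping(self):
        p = SimParams(n_events=1, event_size=(3, 3), seed=4)
        tree, kmap, _ = simulate_labeled_tree(p)
        planted, truth = plant_hgt_events(tree, kmap, p)
        (event,) = truth.events
        assert len(event.recipients) == 3
        assert event.source_kingdom != event.host_kingdom
        assert all(kmap[r] == event.source_kingdom for r in event.recipients)
        assert set(planted.leaf_labels()) == set(tree.leaf_labels())

    def test_events_disjoint(self):
        p = SimParams(seed=6)
        tree, kmap, _ = simulate_labeled_tree(p)
        _, truth = plant_hgt_events(tree, kmap, p)
        seen = set()
        for e in truth.events:
            assert not (set(e.recipients) & seen)
            seen |= set(e.recipients)

    def test_infeasible_event_errors(self):
        p = SimParams(leaves_per_kingdom=3, n_events=5, event_size=(3, 3), seed=0)
        tree, kmap, _ = simulate_labeled_tree(p)
        with pytest.raises(ValueError, match="eligible"):
            plant_hgt_events(tree, kmap, p)


def write_newick_topology(tree):
    t = tree.copy()
    for n in t.postorder():
        n.length = None
    return write_newick(t)


class TestEvolve:
    def test_zero_length_tree_identical_sequences(self):
        t = parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
        seqs = evolve_sequences(t, SimParams(seq_length=50, seed=1))
        assert len(set(seqs.values())) == 1

    def test_missing_lengths_error(self):
        t = parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError, match="lengths"):
            evolve_sequences(t, SimParams(seed=1))

    def test_identity_decay_matches_closed_form(self):
        """Observed p between two leaves matches the substitution model.

        Per edge of length t the chain keeps a residue with probability
        e^(−t), else jumps uniformly among the other 19; composing the two
        leaf edges gives P(same) = 1/20 + (19/20)·λ(t1)·λ(t2) with
        λ(t) = (20·e^(−t) − 1)/19.
        """
        t1, t2, L = 0.3, 0.5, 20000
        tree = parse_newick(f"(A:{t1},B:{t2});")
        seqs = evolve_sequences(tree, SimParams(seq_length=L, seed=11))
        diff = sum(a != b for a, b in zip(seqs["A"], seqs["B"])) / L
        lam = lambda t: (20 * math.exp(-t) - 1) / 19
        p_expected = 1 - (1 / 20 + (19 / 20) * lam(t1) * lam(t2))
        se = math.sqrt(p_expected * (1 - p_expected) / L)
        assert abs(diff - p_expected) < 3 * se

    def test_nj_recovers_branch_lengths_within_ten_percent(self):
        tree = parse_newick("((A:0.12,B:0.2):0.15,(C:0.25,D:0.1):0.08);")
        seqs = evolve_sequences(tree, SimParams(seq_length=5000, seed=21))
        from hgtscan.infer import nj_tree

        dm = poisson_distance(true_alignment(seqs))
        est = {lf.label: lf.length for lf in nj_tree(dm).leaves()}
        truth = {"A": 0.12, "B": 0.2, "C": 0.25, "D": 0.1}
        for k, v in truth.items():
            assert est[k] == pytest.approx(v, rel=0.10, abs=0.01)


class TestPerturb:
    def base(self, seed=0, n=5, L=60):
        rng = np.random.default_rng(seed)
        rows = tuple(
            "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=L))
            for _ in range(n)
        )
        from hgtscan.alignment import Alignment

        return Alignment(tuple(f"s{i}" for i in range(n)), rows)

    def test_rate_zero_identity(self):
        a = self.base()
        assert perturb_alignment(a, 0.0, seed=1) == a

    @pytest.mark.parametrize("rate", [0.1, 0.5, 1.0])
    def test_ungapped_sequences_preserved(self, rate):
        a = self.base()
        b = perturb_alignment(a, rate, seed=2)
        assert b.ungapped_all() == a.ungapped_all()

    def test_perturbed_loses_mos_to_original(self):
        a = self.base(L=100)
        b = perturb_alignment(a, 0.5, seed=3)
        scores, best = mos_scores([a, a, b])
        assert best in (0, 1)
        assert scores[0] > scores[2]

    def test_deterministic_per_seed(self):
        a = self.base()
        assert perturb_alignment(a, 0.3, seed=5) == perturb_alignment(a, 0.3, seed=5)
        assert perturb_alignment(a, 0.3, seed=5) != perturb_alignment(a, 0.3, seed=6)


class TestRecovery:
    def truth(self):
        tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        return SyntheticTruth(
            events=[
                PlantedEvent(("a", "b"), "Plantae", "Bacteria"),
                PlantedEvent(("c",), "Plantae", "Bacteria"),
            ],
            tree=tree,
            records=[],
        )

    def test_exact_calls(self):
        t = self.truth()
        rs = evaluate_recovery(t, {"a", "b", "c"}, [("a", "b"), ("c",)])
        assert rs.leaf_precision == rs.leaf_recall == 1.0
        assert rs.event_precision == rs.event_recall == 1.0

    def test_no_calls_convention(self):
        rs = evaluate_recovery(self.truth(), set(), [])
        assert rs.leaf_precision == 1.0
        assert rs.leaf_recall == 0.0
        assert rs.event_precision == 1.0

    def test_partial_recall(self):
        rs = evaluate_recovery(self.truth(), {"a", "c"}, [("a",), ("c",)])
        assert rs.leaf_precision == 1.0
        assert rs.leaf_recall == pytest.approx(2 / 3)
        # ("a",) vs ("a","b") has Jaccard 0.5 → matches at the threshold
        assert rs.event_recall == 1.0

    def test_false_calls_lower_precision(self):
        rs = evaluate_recovery(self.truth(), {"a", "b", "d"}, [("a", "b", "d")])
        assert rs.leaf_precision == pytest.approx(2 / 3)
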