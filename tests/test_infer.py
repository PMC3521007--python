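"""Distances, neighbor joining, parsimony scoring/search, bootstrap."""

import math

import numpy as np
import pytest

from hgtscan.alignment import Alignment
from hgtscan.infer import (
    DistanceMatrix,
    bootstrap,
    fitch_score,
    mp_search,
    nj_tree,
    p_distance,
    poisson_correct,
    sankoff_score,
)
from hgtscan.trees import (
    Bipartition,
    bipartitions,
    pairwise_leaf_distances,
    parse_newick,
)

from conftest import all_unrooted_topologies, random_protein_alignment, random_tree


def aln(**rows):
    return Alignment(tuple(rows), tuple(rows.values()))


class TestPDistance:
    def test_one_difference_in_four(self):
        d = p_distance(aln(A="AAAA", B="AAAT"))
        assert d.matrix[0, 1] == 0.25

    def test_identical_sequences(self):
        d = p_distance(aln(A="ACDE", B="ACDE"))
        assert d.matrix[0, 1] == 0.0

    def test_complete_vs_pairwise_with_gaps(self):
        # gap in C's first column: complete deletion drops it for everyone
        a = aln(A="AAT", B="AAA", C="-AA")
        comp = p_distance(a, "complete")
        pair = p_distance(a, "pairwise")
        iA, iB = 0, 1
        assert comp.matrix[iA, iB] == pytest.approx(0.5)  # 1 diff / 2 sites
        assert pair.matrix[iA, iB] == pytest.approx(1 / 3)  # 1 diff / 3 sites

    def test_no_comparable_sites_names_pair(self):
        with pytest.raises(ValueError, match="A.*B|B.*A"):
            p_distance(aln(A="A--", B="--A"), "pairwise")


class TestPoisson:
    def test_zero(self):
        assert poisson_correct(0.0) == 0.0

    def test_quarter(self):
        assert poisson_correct(0.25) == pytest.approx(-math.log(0.75))

    def test_closed_form_inverse(self):
        assert poisson_correct(1 - math.exp(-1)) == pytest.approx(1.0)

    @pytest.mark.parametrize("p", [1.0, 1.5, -0.1])
    def test_out_of_range(self, p):
        with pytest.raises(ValueError):
            poisson_correct(p)


class TestNJ:
    def test_additive_quartet(self):
        """Hand-built additive matrix from ((A:1,B:2):1,(C:3,D:4))."""
        ids = ("A", "B", "C", "D")
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        t = nj_tree(DistanceMatrix(ids, D))
        assert bipartitions(t) == {Bipartition({"A", "B"}, ids)}
        lengths = {lf.label: lf.length for lf in t.leaves()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
        dists = pairwise_leaf_distances(t)
        assert dists[("A", "B")] == pytest.approx(3.0)
        assert dists[("C", "D")] == pytest.approx(7.0)

    def test_three_taxa_three_point(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = nj_tree(DistanceMatrix(("A", "B", "C"), D))
        lengths = {lf.label: lf.length for lf in t.leaves()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_fewer_than_three_taxa_error(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0.0]])))

    @pytest.mark.parametrize("seed", range(5))
    def test_taxon_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(8)]
        t = random_tree(labels, rng)
        dists = pairwise_leaf_distances(t)

        def matrix(order):
            D = np.zeros((len(order), len(order)))
            for i, a in enumerate(order):
                for j, b in enumerate(order):
                    if i < j:
                        D[i, j] = D[j, i] = dists[tuple(sorted((a, b)))]
            return DistanceMatrix(tuple(order), D)

        base = bipartitions(nj_tree(matrix(labels)))
        perm = list(rng.permutation(labels))
        assert bipartitions(nj_tree(matrix(perm))) == base

    def test_agrees_with_skbio_on_additive_input(self):
        """Independent NJ implementation recovers the same topology."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        labels = [f"t{i}" for i in range(9)]
        t = random_tree(labels, rng)
        dists = pairwise_leaf_distances(t)
        D = np.zeros((9, 9))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    D[i, j] = D[j, i] = dists[tuple(sorted((a, b)))]
        ours = nj_tree(DistanceMatrix(tuple(labels), D))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        from hgtscan.trees import parse_newick as pn

        their_tree = pn(str(theirs))
        assert bipartitions(their_tree) == bipartitions(ours)


class TestFitch:
    def test_two_state_quartet(self):
        t = parse_newick("((A,B),(C,D));")
        assert fitch_score(t, aln(A="R", B="R", C="K", D="K")) == 1

    def test_constant_column(self):
        t = parse_newick("((A,B),(C,D));")
        assert fitch_score(t, aln(A="G", B="G", C="G", D="G")) == 0

    def test_four_distinct_states(self):
        t = parse_newick("((A,B),(C,D));")
        assert fitch_score(t, aln(A="R", B="K", C="D", D="E")) == 3

    def test_gaps_are_missing_data(self):
        t = parse_newick("((A,B),(C,D));")
        assert fitch_score(t, aln(A="R", B="-", C="K", D="-")) == 1

    def test_leaf_mismatch_errors(self):
        t = parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError, match="differ"):
            fitch_score(t, aln(A="R", B="R", C="K", Z="K"))

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_sankoff_on_random_trees(self, seed):
        """Fitch (bitmask) equals the uniform-cost Sankoff DP."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 10))
        labels = [f"t{i}" for i in range(n)]
        t = random_tree(labels, rng)
        a = random_protein_alignment(labels, 25, rng, alphabet="ACDEF-")
        assert fitch_score(t, a) == sankoff_score(t, a)

    def test_sankoff_handles_polytomies(self):
        t = parse_newick("((A,B,C),(D,E));")
        assert sankoff_score(t, aln(A="R", B="R", C="R", D="K", E="K")) == 1
        with pytest.raises(ValueError, match="binary"):
            fitch_score(t, aln(A="R", B="R", C="R", D="K", E="K"))


class TestMPSearch:
    def test_congruent_quartet_finds_global_optimum(self):
        a = aln(A="RRRKK", B="RRRKK", C="KKKRR", D="KKKRR")
        res = mp_search(a)
        best = min(
            fitch_score(t, a) for t in all_unrooted_topologies(list(a.ids))
        )
        assert res.score == best
        assert bipartitions(res.tree) == {
            Bipartition({"A", "B"}, a.ids)
        }

    def test_constant_alignment_warns_and_returns_start(self):
        a = aln(A="GGG", B="GGG", C="GGG", D="GGG")
        with pytest.warns(UserWarning, match="informative"):
            res = mp_search(a)
        assert res.score == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_never_worse_than_start_and_matches_tied_scores(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(6)]
        a = random_protein_alignment(labels, 12, rng, alphabet="ACD")
        res = mp_search(a)
        start_score = fitch_score(mp_search(a, start=None).tree, a)
        assert res.score <= start_score
        for t in res.tied:
            assert fitch_score(t, a) == res.score


def diverged_alignment(ids, length, rng, rate=0.15):
    """Sequences within moderate divergence of one ancestral sequence."""
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    base = rng.integers(0, 20, size=length)
    rows = []
    for _ in ids:
        seq = base.copy()
        hit = rng.random(length) < rate
        seq[hit] = (seq[hit] + rng.integers(1, 20, size=int(hit.sum()))) % 20
        rows.append("".join(alphabet[seq]))
    return Alignment(tuple(ids), tuple(rows))


class TestBootstrap:
    def test_replicate_count_validation(self):
        a = aln(A="RK", B="RK", C="KR", D="KR")
        with pytest.raises(ValueError):
            bootstrap(a, n=0)

    def test_clean_quartet_signal_high_support(self):
        rng = np.random.default_rng(0)
        cols = [("G", "G", "G", "G")] * 40
        for _ in range(20):
            x, y = rng.choice(list("ACDEFHIK"), size=2, replace=False)
            cols.append((x, x, y, y))
        rows = ["".join(c[i] for c in cols) for i in range(4)]
        a = Alignment(("A", "B", "C", "D"), tuple(rows))
        res = bootstrap(a, "nj", n=100, seed=5)
        bp = Bipartition({"A", "B"}, a.ids)
        assert res.supports[bp] >= 95.0

    def test_supports_bounded_and_deterministic(self):
        rng = np.random.default_rng(3)
        a = diverged_alignment([f"t{i}" for i in range(6)], 60, rng)
        r1 = bootstrap(a, "nj", n=30, seed=9)
        r2 = bootstrap(a, "nj", n=30, seed=9)
        assert r1.supports == r2.supports
        assert all(0.0 <= v <= 100.0 for v in r1.supports.values())
        r3 = bootstrap(a, "nj", n=30, seed=10)
        assert bipartitions(r3.tree) == bipartitions(r1.tree)

    def test_supports_attached_to_tree_nodes(self):
        rng = np.random.default_rng(4)
        a = diverged_alignment([f"t{i}" for i in range(5)], 50, rng, rate=0.3)
        res = bootstrap(a, "mp", n=20, seed=1)
        annotated = [
            n for n in res.tree.postorder() if n.supports is not None
        ]
        assert len(annotated) == len(res.supports)
        assert all(s[0][0] == "MP" for s in (n.supports for n in annotated))

    def test_majority_consensus_mode(self):
        rng = np.random.default_rng(5)
        a = diverged_alignment([f"t{i}" for i in range(6)], 60, rng)
        res = bootstrap(a, "nj", n=30, seed=2, consensus=True)
        # every bipartition of the consensus tree must occur in > half
        assert all(v > 50.0 for v in res.supports.values())
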