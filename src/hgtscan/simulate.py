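"""Synthetic kingdom-labelled gene families with planted inter-kingdom HGT.

The generator builds a random binary gene tree in which each kingdom is
initially monophyletic, plants transfers as subtree-prune-regraft moves
(a donor clade is pruned from its kingdom and regrafted strictly inside a
host kingdom's clade), evolves protein sequences along the tree under a
Poisson/uniform substitution model that matches the pipeline's distance
correction, and fabricates alignment ensembles by locally shifting gap
placement in a known-correct alignment. A truth set records every moved
leaf, so recovery of the planted transfers is directly measurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .alignment import Alignment
from .infer import AA_ALPHABET
from .taxonomy import (
    ARCHAEA,
    BACTERIA,
    OTHER_EUKARYOTE,
    PLANTAE,
    TaxonRecord,
)
from .trees import Tree, TreeNode

__all__ = [
    "SimParams",
    "PlantedEvent",
    "SyntheticTruth",
    "RecoveryScores",
    "simulate_labeled_tree",
    "plant_hgt_events",
    "evolve_sequences",
    "perturb_alignment",
    "evaluate_recovery",
    "make_ensemble",
    "true_alignment",
]

_LINEAGES: dict[str, list[str]] = {
    BACTERIA: ["cellular organisms", "Bacteria", "Proteobacteria"],
    ARCHAEA: ["cellular organisms", "Archaea", "Euryarchaeota"],
    PLANTAE: ["Eukaryota", "Viridiplantae", "Streptophyta"],
    OTHER_EUKARYOTE: ["Eukaryota", "Amoebozoa"],
}

_PREFIXES: dict[str, str] = {
    BACTERIA: "bac",
    ARCHAEA: "arc",
    PLANTAE: "pla",
    OTHER_EUKARYOTE: "euk",
}


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one synthetic gene family.

    Defaults describe a two-kingdom family of 20 leaves per kingdom with
    three planted transfers of 3–6 genes each, 400-residue proteins, and
    moderately divergent branches (exponential lengths, mean 0.08
    substitutions/site per edge).
    """

    kingdoms: tuple[str, ...] = (BACTERIA, PLANTAE)
    leaves_per_kingdom: int = 20
    n_events: int = 3
    event_size: tuple[int, int] = (3, 6)
    seq_length: int = 400
    edge_scale: float = 0.08
    perturb_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.leaves_per_kingdom < 0 or self.n_events < 0:
            raise ValueError("counts must be non-negative")
        if self.seq_length < 1:
            raise ValueError("sequence length must be at least 1")
        if not (0.0 <= self.perturb_rate <= 1.0):
            raise ValueError("perturbation rate must be in [0, 1]")
        if self.edge_scale < 0:
            raise ValueError("edge scale must be non-negative")
        lo, hi = self.event_size
        if not (1 <= lo <= hi):
            raise ValueError("event size range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class PlantedEvent:
    recipients: tuple[str, ...]
    source_kingdom: str
    host_kingdom: str


@dataclass
class SyntheticTruth:
    """Answer key for a planted family."""

    events: list[PlantedEvent]
    tree: Tree
    records: list[TaxonRecord]

    @property
    def transferred_leaves(self) -> set[str]:
        return {lf for e in self.events for lf in e.recipients}


def _join_random(nodes: list[TreeNode], rng: np.random.Generator) -> TreeNode:
    """Uniform sequential pairwise joins (coalescent-style topology)."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(children=[a, b]))
    return nodes[0]


def simulate_labeled_tree(
    params: SimParams,
) -> tuple[Tree, dict[str, str], list[TaxonRecord]]:
    """Random binary gene tree with each kingdom monophyletic.

    Returns the tree, the leaf → kingdom map, and matching taxonomy
    records. Branch lengths are exponential with mean ``edge_scale``.
    Deterministic per seed.
    """
    if len(params.kingdoms) < 2:
        raise ValueError("need at least two kingdoms")
    if len(params.kingdoms) * params.leaves_per_kingdom < 4:
        raise ValueError("need at least four leaves in total")
    rng = np.random.default_rng(params.seed)
    kingdom_map: dict[str, str] = {}
    records: list[TaxonRecord] = []
    roots: list[TreeNode] = []
    for kingdom in params.kingdoms:
        prefix = _PREFIXES.get(kingdom, kingdom[:3].lower())
        leaves = []
        for i in range(params.leaves_per_kingdom):
            name = f"{prefix}{i:03d}"
            leaves.append(TreeNode(label=name))
            kingdom_map[name] = kingdom
            records.append(
                TaxonRecord(
                    id=name,
                    name=f"{kingdom} sp. {i}",
                    lineage=list(_LINEAGES.get(kingdom, ["cellular organisms"])),
                )
            )
        roots.append(_join_random(leaves, rng))
    root = _join_random(roots, rng)
    tree = Tree(root, is_rooted=True)
    for node in tree.postorder():
        if node is not tree.root:
            node.length = float(rng.exponential(params.edge_scale))
    return tree, kingdom_map, records


def plant_hgt_events(
    tree: Tree,
    kingdoms: Mapping[str, str],
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Tree, SyntheticTruth]:
    """Plant ``n_events`` transfers as SPR moves.

    Each event prunes a source-kingdom clade of the configured size and
    regrafts it onto an internal edge strictly inside a different
    kingdom's clade; grafted clades never nest inside one another. The
    input tree is not modified.
    """
    work = tree.copy()
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    lo, hi = params.event_size
    events: list[PlantedEvent] = []
    moved: set[str] = set()
    remaining: dict[str, set[str]] = {}
    for lf in work.leaf_labels():
        k = kingdoms.get(lf)
        if k is not None:
            remaining.setdefault(k, set()).add(lf)

    def mrca(labels: set[str]) -> Optional[TreeNode]:
        if not labels:
            return None
        sets: dict[int, frozenset[str]] = {}
        found = None
        for node in work.postorder():
            if node.is_leaf:
                sets[id(node)] = frozenset([node.label])
            else:
                sets[id(node)] = frozenset().union(
                    *(sets[id(c)] for c in node.children)
                )
            if found is None and labels <= sets[id(node)]:
                found = node
        return found

    for _ in range(params.n_events):
        kingdom_list = list(params.kingdoms)
        order = rng.permutation(len(kingdom_list))
        planted = False
        for si in order:
            source = kingdom_list[si]
            pool = remaining.get(source, set())
            src_mrca = mrca(pool)
            if src_mrca is None or src_mrca.is_leaf:
                continue
            donors = [
                n
                for n in src_mrca.postorder()
                if n is not src_mrca
                and lo <= len(n.leaves()) <= hi
                and {lf.label for lf in n.leaves()} <= pool
            ]
            if not donors:
                continue
            hosts = [k for k in kingdom_list if k != source]
            rng.shuffle(hosts)
            for host in hosts:
                host_pool = remaining.get(host, set())
                host_mrca = mrca(host_pool)
                if host_mrca is None or host_mrca.is_leaf:
                    continue
                # Internal edges strictly inside the host region whose
                # subtrees hold only untouched host-kingdom leaves (grafted
                # clades must not nest inside one another).
                host_edges = [
                    n
                    for n in host_mrca.postorder()
                    if n is not host_mrca
                    and not n.is_leaf
                    and {lf.label for lf in n.leaves()} <= host_pool
                ]
                if not host_edges:
                    continue
                donor = donors[int(rng.integers(len(donors)))]
                target = host_edges[int(rng.integers(len(host_edges)))]
                _spr(work, donor, target, rng, params.edge_scale)
                leaves = tuple(sorted(lf.label for lf in donor.leaves()))
                moved.update(leaves)
                remaining[source] -= set(leaves)
                events.append(
                    PlantedEvent(
                        recipients=leaves, source_kingdom=source, host_kingdom=host
                    )
                )
                planted = True
                break
            if planted:
                break
        if not planted:
            raise ValueError(
                "no eligible donor clade / host edge for a requested event"
            )
    # Rebuild to refresh bookkeeping and validate
    out = Tree(work.root, is_rooted=True)
    truth = SyntheticTruth(events=events, tree=out, records=[])
    return out, truth


def _spr(tree: Tree, donor: TreeNode, target: TreeNode, rng, scale: float) -> None:
    """Prune ``donor`` and regraft onto the edge above ``target``."""
    parent = donor.parent
    if parent is None or target is donor or parent is target:
        raise ValueError("invalid SPR move")
    # prune: splice out donor's parent
    sibs = [c for c in parent.children if c is not donor]
    grand = parent.parent
    if grand is None:
        raise ValueError("cannot prune a child of the root this way")
    if len(sibs) == 1:
        sib = sibs[0]
        sib.length = (sib.length or 0.0) + (parent.length or 0.0)
        idx = grand.children.index(parent)
        grand.children[idx] = sib
        sib.parent = grand
    else:  # polytomy: just drop the donor
        parent.children = sibs
    donor.parent = None
    # regraft: split the edge above target at its midpoint
    tp = target.parent
    assert tp is not None
    t_len = target.length if target.length is not None else float(rng.exponential(scale))
    new = TreeNode(length=t_len / 2.0)
    target.length = t_len / 2.0
    idx = tp.children.index(target)
    tp.children[idx] = new
    new.parent = tp
    new.children = [target, donor]
    target.parent = new
    donor.parent = new
    if donor.length is None:
        donor.length = float(rng.exponential(scale))


def evolve_sequences(
    tree: Tree,
    params: SimParams,
    seed: Optional[int] = None,
) -> dict[str, str]:
    """Evolve protein sequences along the tree.

    Root sequence uniform over the 20 amino acids; along an edge of length
    ``t`` each site substitutes with probability ``1 − e^(−t)`` to a
    uniformly chosen *different* residue — the Poisson-style model whose
    pairwise distances the pipeline's correction inverts (up to multiple
    hits). Deterministic per seed.
    """
    for node in tree.postorder():
        if node is not tree.root and node.length is None:
            raise ValueError("evolve_sequences requires branch lengths everywhere")
    rng = np.random.default_rng(params.seed + 2 if seed is None else seed)
    L = params.seq_length
    seqs: dict[int, np.ndarray] = {
        id(tree.root): rng.integers(0, 20, size=L, dtype=np.int64)
    }
    out: dict[str, str] = {}
    alpha = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)
    for node in tree.preorder():
        if node is not tree.root:
            parent_seq = seqs[id(node.parent)]
            p_sub = 1.0 - np.exp(-float(node.length))
            hit = rng.random(L) < p_sub
            shift = rng.integers(1, 20, size=L, dtype=np.int64)
            seq = parent_seq.copy()
            seq[hit] = (seq[hit] + shift[hit]) % 20
            seqs[id(node)] = seq
        if node.is_leaf:
            out[node.label] = alpha[seqs[id(node)]].tobytes().decode()
    return out


def true_alignment(seqs: Mapping[str, str]) -> Alignment:
    """The evolved site matrix itself (no indels), as an alignment."""
    ids = tuple(sorted(seqs))
    return Alignment(ids, tuple(seqs[i] for i in ids))


def perturb_alignment(
    aln: Alignment, rate: float, seed: Optional[int] = None
) -> Alignment:
    """Locally shift gap placement to fabricate an alternative alignment.

    A ``rate`` fraction of columns is covered by width-2 shift windows: in
    each window a random subset of rows slides one column rightward across
    an inserted gap, destroying the window's cross-subset residue pairs
    and asserting shifted (false) ones, while every ungapped sequence is
    preserved. ``rate`` 0 returns the alignment unchanged.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    if rate == 0.0 or aln.n_cols < 2 or aln.n_rows < 2:
        return aln
    rng = np.random.default_rng(seed)
    L = aln.n_cols
    n_windows = max(1, int(round(rate * L / 2.0)))
    starts: list[int] = []
    occupied = np.zeros(L, dtype=bool)
    candidates = rng.permutation(L - 1)
    for c in candidates:
        if len(starts) >= n_windows:
            break
        if not occupied[c] and not occupied[c + 1]:
            starts.append(int(c))
            occupied[c] = occupied[c + 1] = True
    starts.sort()

    rows = [list(r) for r in aln.rows]
    n = aln.n_rows
    out_rows: list[list[str]] = [[] for _ in range(n)]
    prev = 0
    for c in starts:
        shifted = rng.random(n) < 0.5
        if shifted.all():
            shifted[int(rng.integers(n))] = False
        if not shifted.any():
            shifted[int(rng.integers(n))] = True
        for i in range(n):
            out_rows[i].extend(rows[i][prev:c])
            a, b = rows[i][c], rows[i][c + 1]
            if shifted[i]:
                out_rows[i].extend(["-", a, b])
            else:
                out_rows[i].extend([a, b, "-"])
        prev = c + 2
    for i in range(n):
        out_rows[i].extend(rows[i][prev:])
    return Alignment(aln.ids, tuple("".join(r) for r in out_rows))


def make_ensemble(
    aln: Alignment, n_others: int, rate: float, seed: int
) -> list[Alignment]:
    """The true alignment plus ``n_others`` independent perturbations."""
    return [aln] + [
        perturb_alignment(aln, rate, seed=seed + 10 + k) for k in range(n_others)
    ]


@dataclass
class RecoveryScores:
    """Leaf- and event-level agreement between calls and planted truth."""

    leaf_precision: float
    leaf_recall: float
    event_precision: float
    event_recall: float
    n_true_leaves: int
    n_called_leaves: int
    n_true_events: int
    n_called_events: int


def evaluate_recovery(
    truth: SyntheticTruth,
    called_leaves: set[str],
    called_events: Sequence[Sequence[str]] = (),
    jaccard: float = 0.5,
) -> RecoveryScores:
    """Precision/recall of confirmed leaves and events against the truth.

    Event matching pairs a called event with a planted one when the
    Jaccard overlap of their member sets is ≥ ``jaccard``; each side
    matches at most once. Empty calls have precision 1 by convention.
    """
    true_leaves = truth.transferred_leaves
    tp = len(called_leaves & true_leaves)
    leaf_precision = tp / len(called_leaves) if called_leaves else 1.0
    leaf_recall = tp / len(true_leaves) if true_leaves else 1.0

    remaining = [set(e.recipients) for e in truth.events]
    matched = 0
    for ev in called_events:
        ev_set = set(ev)
        best_i, best_j = -1, 0.0
        for i, t in enumerate(remaining):
            inter = len(ev_set & t)
            union = len(ev_set | t)
            jac = inter / union if union else 0.0
            if jac > best_j:
                best_i, best_j = i, jac
        if best_i >= 0 and best_j >= jaccard:
            matched += 1
            remaining.pop(best_i)
    event_precision = matched / len(called_events) if called_events else 1.0
    event_recall = matched / len(truth.events) if truth.events else 1.0
    return RecoveryScores(
        leaf_precision=leaf_precision,
        leaf_recall=leaf_recall,
        event_precision=event_precision,
        event_recall=event_recall,
        n_true_leaves=len(true_leaves),
        n_called_leaves=len(called_leaves),
        n_true_events=len(truth.events),
        n_called_events=len(called_events),
    )
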