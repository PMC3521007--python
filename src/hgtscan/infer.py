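"""Tree inference: NJ on Poisson-corrected protein distances, and maximum
parsimony via Fitch scoring with close-neighbor-interchange (CNI) search,
each with nonparametric bootstrap.

Distances use the Poisson correction ``d = -ln(1 - p)``, converting the
observed proportion of differing amino-acid sites into expected
substitutions per site under a no-multiple-hit-correction-free Poisson
model. Gap handling for distances defaults to complete deletion (drop any
column containing a gap); gaps in parsimony are missing data, not a 21st
state.

The CNI search is a deterministic hill-climb over the nearest-neighbor-
interchange neighborhood, started from the NJ topology, accepting only
strict score decreases, and returning every co-optimal tree seen during
the final (non-improving) sweep.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alignment import Alignment, GAP_CHARS
from .trees import (
    Bipartition,
    Tree,
    TreeNode,
    bipartitions,
    tree_from_bipartitions,
)

__all__ = [
    "AA_ALPHABET",
    "DistanceMatrix",
    "BootstrapResult",
    "MPResult",
    "p_distance",
    "poisson_correct",
    "poisson_distance",
    "nj_tree",
    "fitch_score",
    "sankoff_score",
    "mp_search",
    "bootstrap",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {c: i for i, c in enumerate(AA_ALPHABET)}
_MISSING = 255
_FULL_MASK = np.uint32((1 << len(AA_ALPHABET)) - 1)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with the deletion mode that produced them."""

    ids: tuple[str, ...]
    matrix: np.ndarray
    mode: str = "complete"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("distances must be finite and non-negative")
        self.matrix = m

    def to_phylip(self) -> str:
        lines = [str(len(self.ids))]
        for i, sid in enumerate(self.ids):
            row = " ".join(f"{x:.6f}" for x in self.matrix[i])
            lines.append(f"{sid}  {row}")
        return "\n".join(lines) + "\n"


def _encode(aln: Alignment) -> np.ndarray:
    """Rows × columns uint8 codes; gaps and non-standard letters = missing."""
    out = np.full((aln.n_rows, aln.n_cols), _MISSING, dtype=np.uint8)
    for i, row in enumerate(aln.rows):
        for j, ch in enumerate(row):
            code = _AA_INDEX.get(ch.upper())
            if ch not in GAP_CHARS and code is not None:
                out[i, j] = code
    return out


def p_distance(aln: Alignment, mode: str = "complete") -> DistanceMatrix:
    """Proportion of differing sites per sequence pair.

    ``complete`` removes every column containing a gap/missing residue
    before comparison; ``pairwise`` compares the mutually present sites of
    each pair. A pair left with zero comparable sites is an error naming
    the pair.
    """
    if aln.n_rows < 2:
        raise ValueError("p-distance needs at least two sequences")
    if mode not in ("complete", "pairwise"):
        raise ValueError(f"unknown deletion mode: {mode!r}")
    X = _encode(aln)
    n = aln.n_rows
    present = X != _MISSING
    if mode == "complete":
        keep = present.all(axis=0)
        X = X[:, keep]
        present = present[:, keep]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            total = int(both.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            diff = int((X[i, both] != X[j, both]).sum())
            D[i, j] = D[j, i] = diff / total
    return DistanceMatrix(aln.ids, D, mode)


def poisson_correct(p: float) -> float:
    """Poisson-corrected distance ``d = -ln(1 - p)`` for ``0 <= p < 1``."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"proportion of differences must be in [0, 1); got {p}")
    return -math.log1p(-p)


def poisson_distance(aln: Alignment, mode: str = "complete") -> DistanceMatrix:
    """Poisson-corrected protein distance matrix."""
    pm = p_distance(aln, mode)
    d = np.zeros_like(pm.matrix)
    n = len(pm.ids)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = poisson_correct(pm.matrix[i, j])
    return DistanceMatrix(pm.ids, d, mode)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbor joining on the Q-criterion.

    Negative branch-length estimates are clamped to 0; Q ties break toward
    the lexicographically smallest pair of cluster labels (a cluster is
    labelled by its smallest member taxon). Returns an unrooted tree
    (root trifurcation).
    """
    n0 = len(dm.ids)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    D = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=t) for t in dm.ids]
    labels: list[str] = list(dm.ids)  # smallest member taxon per cluster

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best: Optional[tuple[str, str, int, int]] = None
        for i, j in np.argwhere(Q <= qmin + 1e-12):
            if i >= j:
                continue
            key = tuple(sorted((labels[i], labels[j])))
            if best is None or key < best[:2]:
                best = (key[0], key[1], int(i), int(j))
        assert best is not None
        i, j = best[2], best[3]
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(li, 0.0)
        child_j.length = max(lj, 0.0)
        parent = TreeNode(children=[child_i, child_j])
        newd = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = newd[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # Final three-point join
    (a, b, c) = nodes
    da = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    db = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    dc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    a.length, b.length, c.length = (max(da, 0.0), max(db, 0.0), max(dc, 0.0))
    root = TreeNode(children=[a, b, c])
    return Tree(root, is_rooted=False)


# ---------------------------------------------------------------------------
# Parsimony


def _leaf_masks(aln: Alignment) -> np.ndarray:
    """Per-leaf, per-column state bitmasks (missing data = full alphabet)."""
    X = _encode(aln)
    masks = np.where(
        X == _MISSING, _FULL_MASK, np.uint32(1) << X.astype(np.uint32)
    ).astype(np.uint32)
    return masks


def _rooted_binary(tree: Tree) -> TreeNode:
    """A strictly binary rooted view of a (possibly unrooted) binary tree."""
    root = tree.root
    kids = root.children
    if len(kids) == 2:
        top = root
    elif len(kids) == 3:
        top = TreeNode()
        right = TreeNode(children=[kids[1].copy(), kids[2].copy()])
        top.add_child(kids[0].copy())
        top.add_child(right)
    else:
        raise ValueError("Fitch scoring requires a binary tree")
    for node in top.postorder():
        if node.children and len(node.children) != 2:
            raise ValueError(
                "Fitch scoring requires a binary tree; use sankoff_score for "
                "multifurcating trees"
            )
    return top


def fitch_score(tree: Tree, aln: Alignment) -> int:
    """Minimum substitution count over all columns (Fitch, 20-state alphabet).

    Gaps and ambiguous residues are missing data (full state set). The tree
    must be binary (a trifurcating root, i.e. an unrooted binary tree, is
    accepted).
    """
    labels = set(tree.leaf_labels())
    if labels != set(aln.ids):
        raise ValueError("tree leaves and alignment ids differ")
    top = _rooted_binary(tree)
    masks = _leaf_masks(aln)
    row_of = {sid: k for k, sid in enumerate(aln.ids)}
    states: dict[int, np.ndarray] = {}
    score = 0
    for node in top.postorder():
        if node.is_leaf:
            states[id(node)] = masks[row_of[node.label]]
        else:
            l, r = (states[id(c)] for c in node.children)
            inter = l & r
            union = l | r
            empty = inter == 0
            score += int(empty.sum())
            states[id(node)] = np.where(empty, union, inter)
    return score


def sankoff_score(tree: Tree, aln: Alignment) -> int:
    """Uniform-cost Sankoff dynamic program; exact for any (multifurcating) tree.

    Serves as the independent check on Fitch scoring and as the scorer for
    polytomous trees.
    """
    labels = set(tree.leaf_labels())
    if labels != set(aln.ids):
        raise ValueError("tree leaves and alignment ids differ")
    X = _encode(aln)
    row_of = {sid: k for k, sid in enumerate(aln.ids)}
    big = 10**6
    nstates = len(AA_ALPHABET)
    costs: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            row = X[row_of[node.label]]
            c = np.full((nstates, len(row)), big, dtype=np.int64)
            obs = row != _MISSING
            c[:, ~obs] = 0
            c[row[obs].astype(int), np.nonzero(obs)[0]] = 0
            costs[id(node)] = c
        else:
            total = np.zeros((nstates, X.shape[1]), dtype=np.int64)
            for child in node.children:
                cc = costs[id(child)]
                m = cc.min(axis=0)
                total += np.minimum(cc, m + 1)
            costs[id(node)] = total
    return int(costs[id(tree.root)].min(axis=0).sum())


# ---------------------------------------------------------------------------
# CNI (NNI hill-climb) search


class _SearchTree:
    """Array-backed rooted-binary tree for fast NNI + Fitch evaluation.

    Rooted on the pendant edge of a reference leaf: root has children
    (ref leaf, rest). Leaves are 0..n-1 in alignment-row order.
    """

    def __init__(self, n_leaves: int):
        self.n = n_leaves
        size = 2 * n_leaves - 1
        self.left = np.full(size, -1, dtype=np.int64)
        self.right = np.full(size, -1, dtype=np.int64)
        self.parent = np.full(size, -1, dtype=np.int64)
        self.root = -1

    def children(self, v: int) -> tuple[int, int]:
        return int(self.left[v]), int(self.right[v])

    def is_leaf(self, v: int) -> bool:
        return self.left[v] < 0

    def postorder_internal(self) -> list[int]:
        order: list[int] = []
        stack = [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if self.is_leaf(v):
                continue
            if done:
                order.append(v)
            else:
                stack.append((v, True))
                stack.append((int(self.left[v]), False))
                stack.append((int(self.right[v]), False))
        return order

    def replace_child(self, p: int, old: int, new: int) -> None:
        if self.left[p] == old:
            self.left[p] = new
        else:
            self.right[p] = new
        self.parent[new] = p

    def internal_edges(self) -> list[int]:
        """Child endpoints of unrooted-internal edges (internal, non-root-child)."""
        return [
            v
            for v in range(2 * self.n - 1)
            if not self.is_leaf(v)
            and v != self.root
            and self.parent[v] != self.root
        ]

    def sibling(self, v: int) -> int:
        p = int(self.parent[v])
        return int(self.right[p]) if self.left[p] == v else int(self.left[p])

    def swap(self, a: int, b: int) -> None:
        """Exchange two subtrees hanging from different parents."""
        pa, pb = int(self.parent[a]), int(self.parent[b])
        self.replace_child(pa, a, b)
        self.replace_child(pb, b, a)


def _search_tree_from(tree: Tree, taxa: Sequence[str]) -> _SearchTree:
    """Convert an unrooted binary ``Tree`` into the search representation."""
    index = {t: i for i, t in enumerate(taxa)}
    st = _SearchTree(len(taxa))
    counter = [len(taxa)]

    # Undirected adjacency over the Tree nodes
    adj: dict[int, list[TreeNode]] = {}
    by_id: dict[int, TreeNode] = {}
    for node in tree.postorder():
        by_id[id(node)] = node
        adj.setdefault(id(node), [])
        for c in node.children:
            adj[id(node)].append(c)
            adj.setdefault(id(c), []).append(node)

    ref = tree.find_leaf(taxa[0])
    start = adj[id(ref)][0]

    def build(node: TreeNode, came_from: TreeNode) -> int:
        nbrs = [x for x in adj[id(node)] if x is not came_from]
        if not nbrs:
            return index[node.label]
        if len(nbrs) != 2:
            raise ValueError("CNI search requires a binary tree")
        v = counter[0]
        counter[0] += 1
        a = build(nbrs[0], node)
        b = build(nbrs[1], node)
        st.left[v], st.right[v] = a, b
        st.parent[a] = st.parent[b] = v
        return v

    top = build(start, ref)
    root = counter[0]
    counter[0] += 1
    st.left[root], st.right[root] = index[taxa[0]], top
    st.parent[index[taxa[0]]] = st.parent[top] = root
    st.root = root
    return st


def _search_tree_to_tree(st: _SearchTree, taxa: Sequence[str]) -> Tree:
    def build(v: int) -> TreeNode:
        if st.is_leaf(v):
            return TreeNode(label=taxa[v])
        l, r = st.children(v)
        return TreeNode(children=[build(l), build(r)])

    ref = TreeNode(label=taxa[int(st.left[st.root])]) if st.is_leaf(
        int(st.left[st.root])
    ) else build(int(st.left[st.root]))
    top = int(st.right[st.root])
    if st.is_leaf(top):
        root = TreeNode(children=[ref, build(top)])
        return Tree(root, is_rooted=False)
    l, r = st.children(top)
    root = TreeNode(children=[build(l), build(r), ref])
    return Tree(root, is_rooted=False)


class _FitchEvaluator:
    """Vectorized Fitch scorer with incremental rescoring along NNI paths.

    After :meth:`full`, per-node state rows and change counts are valid for
    the committed topology; an NNI swap only dirties the lower endpoint of
    the swapped edge and its ancestors, so a candidate move is scored by
    recomputing that path and undone by restoring the saved rows.
    """

    def __init__(self, masks: np.ndarray, base_score: int):
        self.masks = masks  # (n_leaves, C) uint32
        self.base = base_score
        n, C = masks.shape
        self.states = np.zeros((2 * n - 1, C), dtype=np.uint32)
        self.states[:n] = masks
        self.counts = [0] * (2 * n - 1)
        self.total = 0
        # scratch rows to keep the hot path allocation-free
        self._inter = np.zeros(C, dtype=np.uint32)
        self._empty = np.zeros(C, dtype=bool)
        self._filled = np.zeros(C, dtype=bool)

    def _update_node(self, st: _SearchTree, v: int) -> None:
        states = self.states
        inter, empty, filled = self._inter, self._empty, self._filled
        l, r = st.left[v], st.right[v]
        np.bitwise_and(states[l], states[r], out=inter)
        np.equal(inter, 0, out=empty)
        self.counts[v] = int(np.count_nonzero(empty))
        np.bitwise_or(states[l], states[r], out=states[v])
        np.logical_not(empty, out=filled)
        np.copyto(states[v], inter, where=filled)

    def full(self, st: _SearchTree) -> int:
        for v in st.postorder_internal():
            self._update_node(st, v)
        self.total = self.base + int(
            sum(self.counts[v] for v in st.postorder_internal())
        )
        return self.total

    def apply_swap(self, st: _SearchTree, a: int, b: int):
        """Apply an NNI swap and rescore; returns an undo token.

        The dirty region is the root-bound chain from the swapped edge;
        recomputation stops as soon as a node's state set and change count
        come out unchanged, since ancestors then see identical inputs.
        """
        st.swap(a, b)
        pa, pb = int(st.parent[a]), int(st.parent[b])
        if st.parent[pa] == pb:
            first, second = pa, pb
        elif st.parent[pb] == pa:
            first, second = pb, pa
        else:  # pragma: no cover - only NNI swaps are rescored
            raise ValueError("incremental rescoring requires an NNI swap")
        old_total = self.total
        saved = []
        delta = 0
        v = first
        mandatory = {first, second}
        while v >= 0:
            old_row = self.states[v].copy()
            old_count = int(self.counts[v])
            self._update_node(st, v)
            changed = self.counts[v] != old_count or not np.array_equal(
                self.states[v], old_row
            )
            if changed or v in mandatory:
                saved.append((v, old_row, old_count))
                delta += int(self.counts[v]) - old_count
                v = int(st.parent[v])
            else:
                self.counts[v] = old_count  # nothing actually changed
                break
        self.total = old_total + delta
        return (a, b, saved, old_total)

    def undo_swap(self, st: _SearchTree, token) -> None:
        a, b, saved, old_total = token
        for v, row, count in saved:
            self.states[v] = row
            self.counts[v] = count
        self.total = old_total
        st.swap(a, b)


def _informative_split(aln: Alignment) -> tuple[np.ndarray, int, int]:
    """(masks of informative columns, constant score of the rest, n_informative)."""
    X = _encode(aln)
    masks_all = _leaf_masks(aln)
    informative = []
    constant = 0
    for j in range(X.shape[1]):
        col = X[:, j]
        obs = col[col != _MISSING]
        if obs.size == 0:
            continue
        _, counts = np.unique(obs, return_counts=True)
        if (counts >= 2).sum() >= 2:
            informative.append(j)
        else:
            constant += len(counts) - 1
    masks = masks_all[:, informative] if informative else masks_all[:, :0]
    return np.ascontiguousarray(masks), constant, len(informative)


@dataclass
class MPResult:
    """Outcome of the parsimony search."""

    tree: Tree
    score: int
    tied: list[Tree] = field(default_factory=list)


def mp_search(
    aln: Alignment,
    seed: int = 0,
    start: Optional[Tree] = None,
    deletion: str = "complete",
    max_plateau: int = 8,
    escape_margin: int = 2,
    escape_width: Optional[int] = None,
) -> MPResult:
    """Maximum-parsimony search by CNI (NNI hill-climb) from the NJ topology.

    Deterministic for fixed inputs; ``seed`` is accepted for interface
    symmetry with the bootstrap but the search itself draws no random
    numbers. Returns the local optimum and every co-optimal tree visited
    during the final sweep (the optimum first).
    """
    if aln.n_rows < 4:
        raise ValueError("parsimony search needs at least four sequences")
    masks, base, n_inf = _informative_split(aln)
    if start is None:
        try:
            dm = poisson_distance(aln, deletion)
        except ValueError:
            dm = p_distance(aln, deletion)
        start = nj_tree(dm)
    if n_inf == 0:
        warnings.warn(
            "alignment has no parsimony-informative columns; returning the "
            "start (NJ) topology",
            stacklevel=2,
        )
        return MPResult(tree=start, score=base, tied=[start])
    return _mp_search_core(
        list(aln.ids), masks, base, start, max_plateau, escape_margin,
        escape_width,
    )


def _mp_search_core(
    taxa: list[str],
    masks: np.ndarray,
    base: int,
    start: Tree,
    max_plateau: int = 8,
    escape_margin: int = 2,
    escape_width: Optional[int] = None,
) -> MPResult:
    ev = _FitchEvaluator(masks, base)
    score = ev.full(_search_tree_from(start, taxa))

    # Hill-climb accepting strict decreases. Equal-score neighbors join a
    # bounded plateau whose members are also expanded, and at convergence a
    # second interchange is probed through the best non-improving
    # neighbors — the "close neighbor" part of CNI — so tied or shallow
    # rearrangement paths cannot trap the search in a spurious local
    # optimum. Moves are scored incrementally along the dirtied path.
    # Effort knobs: ``max_plateau`` bounds the tied-tree set that is
    # expanded; ``escape_margin``/``escape_width`` bound the two-step probe
    # (width defaults to a multiple of the NNI neighborhood of one tree).
    if escape_width is None:
        escape_width = min(4 * (len(taxa) - 3), 12)

    def neighbor_moves(st: _SearchTree):
        for c in st.internal_edges():
            s = st.sibling(c)
            for child in (int(st.left[c]), int(st.right[c])):
                yield s, child

    def snapshot(st: _SearchTree):
        return (st.left.copy(), st.right.copy(), st.parent.copy(), st.root)

    def restore(snap) -> _SearchTree:
        st = _SearchTree(len(taxa))
        st.left, st.right, st.parent = (
            snap[0].copy(),
            snap[1].copy(),
            snap[2].copy(),
        )
        st.root = snap[3]
        return st

    def signature(st: _SearchTree) -> frozenset:
        sets: dict[int, frozenset[int]] = {}
        n = st.n
        out = []
        for v in st.postorder_internal():
            l, r = st.children(v)
            sl = sets.get(l, frozenset([l]) if l < n else frozenset())
            sr = sets.get(r, frozenset([r]) if r < n else frozenset())
            blk = sl | sr
            sets[v] = blk
            if 1 < len(blk) < n - 1:
                out.append(blk)
        return frozenset(out)

    st0 = _search_tree_from(start, taxa)
    plateau = [snapshot(st0)]
    seen = {signature(st0)}
    while True:
        improved = False
        probe_points: list[tuple[int, int, int, int, int]] = []
        i = 0
        while i < len(plateau):
            st = restore(plateau[i])
            ev.full(st)
            member_idx = i
            i += 1
            for order_idx, (s, child) in enumerate(neighbor_moves(st)):
                token = ev.apply_swap(st, s, child)
                new_score = ev.total
                if new_score < score:
                    score = new_score
                    plateau = [snapshot(st)]
                    seen = {signature(st)}
                    i = 0
                    improved = True
                else:
                    if new_score == score and len(plateau) < max_plateau:
                        key = signature(st)
                        if key not in seen:
                            seen.add(key)
                            plateau.append(snapshot(st))
                    if new_score <= score + escape_margin:
                        probe_points.append(
                            (new_score, member_idx, order_idx, s, child)
                        )
                ev.undo_swap(st, token)
                if improved:
                    break
            if improved:
                break
        if improved:
            continue
        # Escape probe: a second interchange through the best non-improving
        # first-level neighbors recorded during the final sweep.
        escaped = False
        probe_points.sort(key=lambda t: t[:3])
        for lvl1, member_idx, _oi, s1, c1 in probe_points[:escape_width]:
            if lvl1 > score + escape_margin:
                continue
            st = restore(plateau[member_idx])
            ev.full(st)
            t1 = ev.apply_swap(st, s1, c1)
            for s2, c2 in list(neighbor_moves(st)):
                t2 = ev.apply_swap(st, s2, c2)
                if ev.total < score:
                    score = ev.total
                    plateau = [snapshot(st)]
                    seen = {signature(st)}
                    escaped = True
                ev.undo_swap(st, t2)
                if escaped:
                    break
            ev.undo_swap(st, t1)
            if escaped:
                break
        if not escaped:
            tied = [
                _search_tree_to_tree(restore(snap), taxa) for snap in plateau
            ]
            return MPResult(tree=tied[0], score=score, tied=tied)


# ---------------------------------------------------------------------------
# Bootstrap


@dataclass
class BootstrapResult:
    """Point-estimate tree with per-bipartition support percentages."""

    tree: Tree
    supports: dict[Bipartition, float]
    n_replicates: int
    seed: Optional[int]
    method: str


def _distance_from_codes(
    X: np.ndarray, taxa: Sequence[str], mode: str, correct: bool = True
) -> DistanceMatrix:
    """Pairwise (optionally Poisson-corrected) distances from encoded codes."""
    present = X != _MISSING
    if mode == "complete":
        keep = present.all(axis=0)
        X = X[:, keep]
        if X.shape[1] == 0:
            raise ValueError("no comparable sites after complete deletion")
        neq = (X[:, None, :] != X[None, :, :]).sum(-1)
        P = neq / X.shape[1]
    else:
        both = present[:, None, :] & present[None, :, :]
        tot = both.sum(-1)
        off = ~np.eye(len(taxa), dtype=bool)
        if np.any(tot[off] == 0):
            raise ValueError("a sequence pair has no comparable sites")
        neq = ((X[:, None, :] != X[None, :, :]) & both).sum(-1)
        P = neq / np.maximum(tot, 1)
    np.fill_diagonal(P, 0.0)
    if not correct:
        return DistanceMatrix(tuple(taxa), P, mode)
    if np.any(P >= 1.0):
        raise ValueError("saturated p-distance (p >= 1); cannot Poisson-correct")
    return DistanceMatrix(tuple(taxa), -np.log1p(-P), mode)


def _method_tree(aln: Alignment, method: str, deletion: str) -> Tree:
    if method == "nj":
        return nj_tree(poisson_distance(aln, deletion))
    if method == "mp":
        return mp_search(aln, deletion=deletion).tree
    raise ValueError(f"unknown method: {method!r}")


def bootstrap(
    aln: Alignment,
    method: str = "nj",
    n: int = 100,
    seed: Optional[int] = None,
    deletion: str = "complete",
    consensus: bool = False,
) -> BootstrapResult:
    """Column bootstrap: resample alignment columns with replacement ``n``
    times, re-run the method, and report per-bipartition support in percent.

    By default supports map onto the full-data tree; with ``consensus=True``
    the reported tree is instead the majority-rule consensus of the
    replicate trees. Reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("bootstrap needs at least one replicate")
    method = method.lower()
    if method not in ("nj", "mp"):
        raise ValueError(f"unknown method: {method!r}")
    full = _method_tree(aln, method, deletion)
    rng = np.random.default_rng(seed)
    counts: dict[Bipartition, int] = {}
    C = aln.n_cols

    # Precompute the per-column encodings once; replicates only index into
    # them, which keeps 100-replicate runs on 40-taxon families fast.
    X = _encode(aln)
    taxa = list(aln.ids)
    if method == "mp":
        masks_all = _leaf_masks(aln)
        informative = np.zeros(C, dtype=bool)
        const_col = np.zeros(C, dtype=np.int64)
        for j in range(C):
            obs = X[:, j][X[:, j] != _MISSING]
            if obs.size == 0:
                continue
            _, cts = np.unique(obs, return_counts=True)
            if (cts >= 2).sum() >= 2:
                informative[j] = True
            else:
                const_col[j] = len(cts) - 1

    for _ in range(n):
        idx = rng.integers(0, C, size=C)
        try:
            dm = _distance_from_codes(X[:, idx], taxa, deletion)
        except ValueError:
            if method == "nj":
                raise
            dm = _distance_from_codes(X[:, idx], taxa, deletion, correct=False)
        start = nj_tree(dm)
        if method == "nj":
            rep_tree = start
        else:
            info_idx = idx[informative[idx]]
            base = int(const_col[idx].sum())
            if info_idx.size == 0:
                rep_tree = start
            else:
                masks = np.ascontiguousarray(masks_all[:, info_idx])
                rep_tree = _mp_search_core(taxa, masks, base, start).tree
        for bp in bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1

    if consensus:
        majority = {bp for bp, c in counts.items() if c > n / 2}
        report = tree_from_bipartitions(aln.ids, majority)
    else:
        report = full
    supports: dict[Bipartition, float] = {}
    leafset = report.leaf_set()
    blocks: dict[int, frozenset[str]] = {}
    tag = method.upper()
    for node in report.postorder():
        if node.is_leaf:
            blocks[id(node)] = frozenset([node.label])
            continue
        blocks[id(node)] = frozenset().union(*(blocks[id(c)] for c in node.children))
        if node is report.root:
            continue
        blk = blocks[id(node)]
        if 1 < len(blk) < len(leafset) - 1:
            bp = Bipartition(blk, leafset)
            pct = 100.0 * counts.get(bp, 0) / n
            supports[bp] = pct
            node.supports = [(tag, pct)]
    return BootstrapResult(
        tree=report, supports=supports, n_replicates=n, seed=seed, method=method
    )
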