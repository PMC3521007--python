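"""Stage 1: screen a gene-family tree for leaves nested in a foreign kingdom.

A leaf (or a maximal same-kingdom group of leaves) is an inter-kingdom HGT
candidate when it is *wrapped* by another kingdom's branches: leaves of the
host kingdom occur in at least two distinct directions around the group's
attachment node, so the group is genuinely inside the host clade rather
than merely sister to it. This two-sided reading makes the screen exact on
kingdom-monophyletic trees (no kingdom can surround a group it does not
contain), which is the screen's false-positive control.

The reported host clade is the smallest ancestor with at least
``min_native`` host-kingdom leaves whose non-candidate composition meets
the purity threshold; purity excludes the leaves of other wrapped groups
so that multiple transfers into one clade do not mask each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

from .taxonomy import UNKNOWN
from .trees import Tree, TreeNode, midpoint_root, outgroup_root

__all__ = [
    "ScreenParams",
    "HGTCandidate",
    "extract_kingdom_subtrees",
    "detect_foreign_leaves",
    "filter_by_length",
    "populate_fragment_lengths",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenParams:
    """Screening thresholds.

    min_native:
        Minimum host-kingdom leaves a host clade must contain (default 3).
    purity:
        Minimum fraction of the host clade's non-candidate known leaves
        that must belong to the host kingdom, in (0, 1].
    min_fragment_length:
        Aligned-fragment length cutoff in amino acids; shorter candidates
        are dropped as dubious (default 300).
    kingdom:
        Restrict the screen to one host kingdom; ``None`` screens all.
    outgroup:
        Taxa used to root unrooted input trees; midpoint rooting is the
        fallback when empty.
    ancient_threshold:
        Minimum member count for an event to be flagged ancient (used by
        the calling stage; kept here so one parameter object travels the
        pipeline).
    """

    min_native: int = 3
    purity: float = 1.0
    min_fragment_length: int = 300
    kingdom: Optional[str] = None
    outgroup: tuple[str, ...] = ()
    ancient_threshold: int = 5

    def __post_init__(self) -> None:
        if self.min_fragment_length <= 0:
            raise ValueError("minimum fragment length must be positive")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity threshold must be in (0, 1]")
        if self.min_native < 1:
            raise ValueError("min_native must be at least 1")


@dataclass
class HGTCandidate:
    """One foreign leaf with its host-clade context."""

    leaf_id: str
    native_kingdom: str
    host_kingdom: str
    host_clade_size: int
    purity: float
    fragment_length: Optional[int] = None
    status: str = "candidate"
    note: str = ""

    def __post_init__(self) -> None:
        if self.native_kingdom == self.host_kingdom:
            raise ValueError("candidate's native and host kingdoms must differ")
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError("purity must be in [0, 1]")


def _known(kingdoms: Mapping[str, str], label: str) -> Optional[str]:
    k = kingdoms.get(label, UNKNOWN)
    return None if k == UNKNOWN else k


def _leafsets(tree: Tree) -> dict[int, frozenset[str]]:
    out: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            out[id(node)] = frozenset([node.label])
        else:
            out[id(node)] = frozenset().union(*(out[id(c)] for c in node.children))
    return out


def ensure_rooted(tree: Tree, params: ScreenParams) -> Tree:
    """Root for screening: configured outgroup first, midpoint otherwise."""
    if params.outgroup:
        return outgroup_root(tree, params.outgroup)
    if tree.is_rooted:
        return tree
    try:
        return midpoint_root(tree)
    except ValueError as exc:
        raise ValueError(
            "cannot root tree for screening: no outgroup configured and "
            f"midpoint rooting failed ({exc})"
        ) from exc


def extract_kingdom_subtrees(
    tree: Tree,
    kingdoms: Mapping[str, str],
    kingdom: str,
    params: ScreenParams,
) -> list[Tree]:
    """Maximal clades dominated by one kingdom.

    A clade qualifies when the fraction of its known-kingdom leaves in
    ``kingdom`` is ≥ the purity threshold and it holds ≥ ``min_native``
    such leaves; of nested qualifying clades only the outermost is
    returned, so results are disjoint.
    """
    present = any(kingdoms.get(lf) == kingdom for lf in tree.leaf_labels())
    if not present:
        logger.warning("kingdom %r absent from tree; no subtrees", kingdom)
        return []
    counts: dict[int, tuple[int, int]] = {}  # node -> (native, known)
    for node in tree.postorder():
        if node.is_leaf:
            k = _known(kingdoms, node.label)
            counts[id(node)] = (int(k == kingdom), int(k is not None))
        else:
            native = sum(counts[id(c)][0] for c in node.children)
            known = sum(counts[id(c)][1] for c in node.children)
            counts[id(node)] = (native, known)

    out: list[Tree] = []

    def qualifies(node: TreeNode) -> bool:
        native, known = counts[id(node)]
        return (
            native >= params.min_native
            and known > 0
            and native / known >= params.purity
        )

    stack = [tree.root]
    while stack:
        node = stack.pop()
        if qualifies(node):
            out.append(Tree(node.copy(), is_rooted=True))
        else:
            stack.extend(node.children)
    return out


def _foreign_groups(
    tree: Tree, kingdoms: Mapping[str, str]
) -> list[tuple[TreeNode, str]]:
    """Maximal clades whose known leaves all share one kingdom.

    Returns (node, kingdom) pairs; a group node's parent always sees more
    than one kingdom. Groups made only of Unknown leaves are skipped.
    """
    kset: dict[int, set[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            k = _known(kingdoms, node.label)
            kset[id(node)] = {k} if k else set()
        else:
            kset[id(node)] = set().union(*(kset[id(c)] for c in node.children))
    groups: list[tuple[TreeNode, str]] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        ks = kset[id(node)]
        if len(ks) == 1 and node is not tree.root:
            groups.append((node, next(iter(ks))))
        elif ks:
            stack.extend(node.children)
    return groups


def detect_foreign_leaves(
    tree: Tree,
    kingdoms: Mapping[str, str],
    params: Optional[ScreenParams] = None,
) -> list[HGTCandidate]:
    """Find every leaf wrapped inside another kingdom's branches.

    A maximal same-kingdom group is called for host kingdom K when

    1. it passes the *wrap test*: K leaves occur in ≥ 2 distinct
       directions around the group's attachment node (so it is inside K's
       branches, not merely sister to them);
    2. it lies strictly inside a *K host region*: a maximal non-root clade
       whose non-candidate known leaves are ≥ purity-threshold K with at
       least ``min_native`` K members. Purity excludes the leaves of
       groups that are themselves wrapped for K, so several transfers
       into one clade do not mask each other — while native groups merely
       sandwiched between two transfers are never candidates, because
       they sit in their own kingdom's region.

    Each candidate leaf is reported once, with the smallest qualifying
    host clade. Unknown-kingdom leaves neither become candidates nor
    count toward purity.
    """
    params = params or ScreenParams()
    rooted = ensure_rooted(tree, params)
    leafsets = _leafsets(rooted)
    all_leaves = leafsets[id(rooted.root)]
    by_kingdom: dict[str, set[str]] = {}
    for lf in all_leaves:
        k = _known(kingdoms, lf)
        if k:
            by_kingdom.setdefault(k, set()).add(lf)
    known_leaves = frozenset().union(*by_kingdom.values()) if by_kingdom else frozenset()

    groups = _foreign_groups(rooted, kingdoms)

    def majority_kingdom(
        block: frozenset[str], excluded: frozenset[str]
    ) -> Optional[str]:
        block = block - excluded
        counts: dict[str, int] = {}
        total = 0
        for k, members in by_kingdom.items():
            c = len(block & members)
            counts[k] = c
            total += c
        if total == 0:
            return None
        best = max(counts, key=lambda k: (counts[k], k))
        return best if counts[best] * 2 > total else None

    # Wrap test (one pass per group): the two nearest informative
    # directions away from the group — its sibling subtrees, then each
    # successive ancestor's siblings — must share one majority kingdom
    # different from the group's own. Direction majorities exclude the
    # leaves of the group's same-kingdom peer groups, so adjacent
    # co-transfers cannot mask each other. A monophyletic kingdom holds
    # leaves in at most one direction seen from outside itself, so the
    # test calls nothing on a kingdom-monophyletic tree.
    group_info: dict[int, tuple[TreeNode, str]] = {
        id(node): (node, native) for node, native in groups if node.parent
    }
    peers_of: dict[str, list[frozenset[str]]] = {}
    for node, native in groups:
        peers_of.setdefault(native, []).append(leafsets[id(node)])

    wrapped_hosts: dict[int, str] = {}
    for gid, (node, native) in group_info.items():
        own = leafsets[id(node)]
        excluded = frozenset().union(
            *(p for p in peers_of[native] if p is not leafsets[id(node)])
        ) if len(peers_of[native]) > 1 else frozenset()
        excluded -= own
        majorities: list[str] = []
        child, anc = node, node.parent
        while anc is not None and len(majorities) < 2:
            for c in anc.children:
                if c is not child and len(majorities) < 2:
                    m = majority_kingdom(leafsets[id(c)], excluded)
                    if m is not None:
                        majorities.append(m)
            child, anc = anc, anc.parent
        if (
            len(majorities) == 2
            and majorities[0] == majorities[1]
            and majorities[0] != native
        ):
            wrapped_hosts[gid] = majorities[0]

    # Per-kingdom purity exclusions: leaves of non-K groups wrapped for K
    excluded_for: dict[str, frozenset[str]] = {}
    for k in by_kingdom:
        excl = [
            leafsets[id(group_info[gid][0])]
            for gid, host in wrapped_hosts.items()
            if host == k and group_info[gid][1] != k
        ]
        excluded_for[k] = frozenset().union(*excl) if excl else frozenset()

    # Host regions: an exclusive top-down partition. A clade is claimed by
    # the strict-majority kingdom of its known leaves when that kingdom
    # has ≥ min_native members and the clade is pure enough once wrapped
    # foreign groups are set aside; descent stops at a claimed clade, so
    # no region can sit inside another kingdom's region.
    region_nodes: dict[str, list[TreeNode]] = {}
    stack = list(rooted.root.children)
    while stack:
        node = stack.pop()
        blk = leafsets[id(node)]
        claimed = False
        k = majority_kingdom(blk, frozenset())
        if k is not None:
            counted = (blk & known_leaves) - excluded_for[k]
            n_k = len(blk & by_kingdom[k])
            if (
                counted
                and n_k >= params.min_native
                and len(counted & by_kingdom[k]) / len(counted) >= params.purity
            ):
                region_nodes.setdefault(k, []).append(node)
                claimed = True
        if not claimed:
            stack.extend(node.children)

    # Candidates: wrapped groups strictly inside a host region of kingdom K
    out: list[HGTCandidate] = []
    for gid, host in wrapped_hosts.items():
        node, native = group_info[gid]
        own = leafsets[id(node)]
        if params.kingdom is not None and host != params.kingdom:
            continue
        inside = any(
            own < leafsets[id(region)] and region is not node
            for region in region_nodes.get(host, [])
        )
        if not inside:
            continue
        host_members = by_kingdom[host]
        excl = excluded_for[host]
        anc = node.parent
        chosen: Optional[tuple[TreeNode, float]] = None
        while anc is not None and anc is not rooted.root:
            rest = leafsets[id(anc)] - own
            non_candidate = (rest & known_leaves) - excl
            n_host = len(non_candidate & host_members)
            purity = (
                n_host / len(non_candidate) if non_candidate else 1.0
            )
            if n_host >= params.min_native and purity >= params.purity:
                chosen = (anc, purity)
                break
            anc = anc.parent
        if chosen is None:
            continue
        clade, purity = chosen
        size = len(leafsets[id(clade)])
        for lf in sorted(own):
            if _known(kingdoms, lf):
                out.append(
                    HGTCandidate(
                        leaf_id=lf,
                        native_kingdom=native,
                        host_kingdom=host,
                        host_clade_size=size,
                        purity=purity,
                    )
                )
    out.sort(key=lambda c: c.leaf_id)
    return out


def populate_fragment_lengths(
    candidates: Sequence[HGTCandidate],
    aligned_lengths: Optional[Mapping[str, int]] = None,
    full_lengths: Optional[Mapping[str, int]] = None,
) -> list[HGTCandidate]:
    """Fill fragment lengths from aligned-region lengths, else full lengths."""
    out = []
    for c in candidates:
        length = None
        if aligned_lengths and c.leaf_id in aligned_lengths:
            length = aligned_lengths[c.leaf_id]
        elif full_lengths and c.leaf_id in full_lengths:
            length = full_lengths[c.leaf_id]
        out.append(replace(c, fragment_length=length))
    return out


def filter_by_length(
    candidates: Sequence[HGTCandidate], params: Optional[ScreenParams] = None
) -> list[HGTCandidate]:
    """Drop candidates whose aligned fragment is shorter than the cutoff.

    A candidate with no recorded length is conservatively retained and
    flagged; removals are logged with the reason.
    """
    params = params or ScreenParams()
    kept: list[HGTCandidate] = []
    for c in candidates:
        if c.fragment_length is None:
            logger.warning(
                "candidate %s has no fragment length; retained with flag",
                c.leaf_id,
            )
            kept.append(replace(c, note="length-missing"))
        elif c.fragment_length >= params.min_fragment_length:
            kept.append(c)
        else:
            logger.info(
                "candidate %s removed: fragment %d aa < %d aa",
                c.leaf_id,
                c.fragment_length,
                params.min_fragment_length,
            )
    return kept
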