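"""Stage 5: confirm screened candidates on the combined tree and count events.

A candidate survives when the reconstructed, method-consensus topology
still shows it wrapped inside the same host kingdom. Because the strict
intersection collapses contested edges into polytomies, a candidate whose
local neighborhood dissolved into a mixed polytomy is *unresolved* rather
than rejected — the combined tree simply does not adjudicate it.

Confirmed foreign leaves are grouped into transfer events: one event per
maximal clade made solely of confirmed leaves sharing a (source, host)
kingdom pair; events with at least ``ancient_threshold`` members are
flagged ancient, mirroring the triangle-marked multi-gene transfers one
sees in published gene-family trees.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional, Sequence

from .screen import HGTCandidate, ScreenParams, detect_foreign_leaves
from .taxonomy import UNKNOWN
from .trees import Tree, root_by_split

__all__ = [
    "HGTEvent",
    "HGTReport",
    "confirm_candidates",
    "group_events",
    "summarize",
]

CONFIRMED = "confirmed"
REJECTED = "rejected"
UNRESOLVED = "unresolved"


@dataclass
class HGTEvent:
    """A maximal group of confirmed foreign leaves counted as one transfer."""

    members: tuple[str, ...]
    source_kingdom: str
    host_kingdom: str
    clade_size: int
    ancient: bool

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class HGTReport:
    """Machine-readable pipeline outcome."""

    statuses: dict[str, str]
    candidates: list[dict]
    events: list[HGTEvent]
    totals_by_kingdom_pair: dict[str, int]
    n_confirmed: int
    n_rejected: int
    n_unresolved: int
    params: dict = field(default_factory=dict)
    tool_version: str = ""

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "statuses": self.statuses,
            "candidates": self.candidates,
            "events": [asdict(e) for e in self.events],
            "totals_by_kingdom_pair": self.totals_by_kingdom_pair,
            "n_confirmed": self.n_confirmed,
            "n_rejected": self.n_rejected,
            "n_unresolved": self.n_unresolved,
            "params": self.params,
            "tool_version": self.tool_version,
        }
        return json.dumps(payload, indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "HGTReport":
        data = json.loads(text)
        events = [
            HGTEvent(
                members=tuple(e["members"]),
                source_kingdom=e["source_kingdom"],
                host_kingdom=e["host_kingdom"],
                clade_size=e["clade_size"],
                ancient=e["ancient"],
            )
            for e in data["events"]
        ]
        return cls(
            statuses=data["statuses"],
            candidates=data["candidates"],
            events=events,
            totals_by_kingdom_pair=data["totals_by_kingdom_pair"],
            n_confirmed=data["n_confirmed"],
            n_rejected=data["n_rejected"],
            n_unresolved=data["n_unresolved"],
            params=data.get("params", {}),
            tool_version=data.get("tool_version", ""),
        )

    @property
    def confirmed_leaves(self) -> set[str]:
        return {lf for lf, s in self.statuses.items() if s == CONFIRMED}


def rooted_view(
    combined: Tree,
    params: Optional[ScreenParams] = None,
    root_split: Optional[set[str]] = None,
) -> Tree:
    """The combined tree under the rooting used for confirmation/grouping.

    Preference order: the configured outgroup, then a carried-over root
    bipartition from the reference tree, then the combined tree's own
    constructed root (combined trees carry no branch lengths, so midpoint
    rooting is unavailable).
    """
    params = params or ScreenParams()
    if params.outgroup:
        return combined  # detect_foreign_leaves roots by outgroup itself
    if root_split:
        return root_by_split(combined, root_split)
    if not combined.is_rooted:
        return Tree(combined.root, is_rooted=True)
    return combined


def _directions_at_parent(tree: Tree, leaf_id: str):
    """Leaf-label sets of the components around the leaf's parent node."""
    target = tree.find_leaf(leaf_id)
    u = target.parent
    if u is None:
        return [], 0
    leafsets: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            leafsets[id(node)] = frozenset([node.label])
        else:
            leafsets[id(node)] = frozenset().union(
                *(leafsets[id(c)] for c in node.children)
            )
    directions = [leafsets[id(c)] for c in u.children if c is not target]
    up = leafsets[id(tree.root)] - leafsets[id(u)]
    if up:
        directions.append(up)
    return directions, len(u.children)


def confirm_candidates(
    combined: Tree,
    kingdoms: Mapping[str, str],
    candidates: Sequence[HGTCandidate],
    params: Optional[ScreenParams] = None,
    root_split: Optional[set[str]] = None,
) -> dict[str, str]:
    """Re-screen candidates on the combined tree.

    confirmed — the leaf is again detected with the same host kingdom;
    unresolved — not re-detected, but its attachment is a polytomy whose
    surroundings touch both the native and the host kingdom (the collapsed
    consensus does not resolve the placement); rejected — otherwise.

    ``root_split`` carries the reference tree's rooting onto the combined
    tree (one side of the reference root bipartition); without it the
    configured outgroup, or the combined tree's own root, is used.
    """
    params = params or ScreenParams()
    tree_leaves = set(combined.leaf_labels())
    missing = [c.leaf_id for c in candidates if c.leaf_id not in tree_leaves]
    if missing:
        raise ValueError(f"candidate leaves missing from combined tree: {missing}")
    view = rooted_view(combined, params, root_split)
    redetected = {
        c.leaf_id: c.host_kingdom
        for c in detect_foreign_leaves(view, kingdoms, params)
    }
    statuses: dict[str, str] = {}
    for cand in candidates:
        if redetected.get(cand.leaf_id) == cand.host_kingdom:
            statuses[cand.leaf_id] = CONFIRMED
            continue
        directions, n_children = _directions_at_parent(combined, cand.leaf_id)
        polytomy = (len(directions) + 1) > 3
        if polytomy:
            kinds = set()
            for d in directions:
                for lf in d:
                    k = kingdoms.get(lf, UNKNOWN)
                    if k != UNKNOWN:
                        kinds.add(k)
            if cand.host_kingdom in kinds:
                statuses[cand.leaf_id] = UNRESOLVED
                continue
        statuses[cand.leaf_id] = REJECTED
    return statuses


def group_events(
    combined: Tree,
    confirmed: Mapping[str, tuple[str, str]],
    params: Optional[ScreenParams] = None,
    root_split: Optional[set[str]] = None,
) -> list[HGTEvent]:
    """Partition confirmed foreign leaves into transfer events.

    ``confirmed`` maps leaf id → (source kingdom, host kingdom). An event
    is a maximal clade consisting solely of confirmed leaves with one
    shared kingdom pair; isolated confirmed leaves form singleton events.
    Same-pair groups hanging side by side from one multifurcation are
    counted as a single event — the collapsed consensus does not separate
    them, so their common origin is not contradicted. The same rooting as
    confirmation is applied (``root_split``).
    """
    params = params or ScreenParams()
    if not confirmed:
        return []
    combined = rooted_view(combined, params, root_split)
    pair_of: dict[int, Optional[tuple[str, str]]] = {}
    leafsets: dict[int, frozenset[str]] = {}
    for node in combined.postorder():
        if node.is_leaf:
            leafsets[id(node)] = frozenset([node.label])
            pair_of[id(node)] = confirmed.get(node.label)
        else:
            leafsets[id(node)] = frozenset().union(
                *(leafsets[id(c)] for c in node.children)
            )
            pairs = {pair_of[id(c)] for c in node.children}
            pair_of[id(node)] = pairs.pop() if len(pairs) == 1 else None

    # Maximal single-pair clades, keyed by their attachment node so that
    # sibling groups under one polytomy coalesce.
    clusters: dict[tuple[int, tuple[str, str]], set[str]] = {}
    stack = [combined.root]
    while stack:
        node = stack.pop()
        pair = pair_of[id(node)]
        if pair is not None and node is not combined.root:
            key = (id(node.parent), pair)
            clusters.setdefault(key, set()).update(leafsets[id(node)])
        else:
            stack.extend(node.children)
    events = [
        HGTEvent(
            members=tuple(sorted(members)),
            source_kingdom=pair[0],
            host_kingdom=pair[1],
            clade_size=len(members),
            ancient=len(members) >= params.ancient_threshold,
        )
        for (_parent, pair), members in clusters.items()
    ]
    events.sort(key=lambda e: e.members)
    return events


def summarize(
    statuses: Mapping[str, str],
    candidates: Sequence[HGTCandidate],
    events: Sequence[HGTEvent],
    params: Optional[ScreenParams] = None,
    extra_params: Optional[Mapping] = None,
) -> HGTReport:
    """Assemble the machine-readable report; totals satisfy conservation
    (confirmed-leaf total equals the sum of event member counts)."""
    from . import __version__

    params = params or ScreenParams()
    totals: dict[str, int] = {}
    for e in events:
        key = f"{e.source_kingdom}->{e.host_kingdom}"
        totals[key] = totals.get(key, 0) + e.size
    n_confirmed = sum(1 for s in statuses.values() if s == CONFIRMED)
    n_event_members = sum(e.size for e in events)
    if events and n_confirmed != n_event_members:
        raise ValueError(
            f"bookkeeping violation: {n_confirmed} confirmed leaves but "
            f"{n_event_members} event members"
        )
    param_echo = {
        "min_native": params.min_native,
        "purity": params.purity,
        "min_fragment_length": params.min_fragment_length,
        "kingdom": params.kingdom,
        "outgroup": list(params.outgroup),
        "ancient_threshold": params.ancient_threshold,
    }
    if extra_params:
        param_echo.update(dict(extra_params))
    return HGTReport(
        statuses=dict(sorted(statuses.items())),
        candidates=[asdict(c) for c in candidates],
        events=list(events),
        totals_by_kingdom_pair=dict(sorted(totals.items())),
        n_confirmed=n_confirmed,
        n_rejected=sum(1 for s in statuses.values() if s == REJECTED),
        n_unresolved=sum(1 for s in statuses.values() if s == UNRESOLVED),
        params=param_echo,
        tool_version=__version__,
    )
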