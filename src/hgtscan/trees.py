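"""Phylogenetic tree data model and Newick I/O.

The tree container used by every pipeline stage: a rooted node structure
that can also represent unrooted topologies (root of degree 3), with
branch lengths in substitutions/site and optional per-method bootstrap
support annotations on internal nodes.

Support annotations serialize in the node-label position as an ordered,
slash-separated list (canonical method order ML/NJ/MP, ``-`` for a method
without a value), e.g. ``(A,B)86/92/-:0.1``.
"""

from __future__ import annotations

import re
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "TreeNode",
    "Tree",
    "Bipartition",
    "NewickError",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "midpoint_root",
    "outgroup_root",
    "METHOD_ORDER",
]

#: Canonical order in which method supports are serialized.
METHOD_ORDER = ("ML", "NJ", "MP")

_FLOAT_RE = re.compile(r"[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?")
_NEEDS_QUOTE_RE = re.compile(r"[\s()\[\]{}/,;:=*'\"`+<>-]")


class NewickError(ValueError):
    """Raised for malformed Newick input; carries the offending position."""

    def __init__(self, message: str, position: Optional[int] = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class TreeNode:
    """A node of a phylogeny.

    Attributes
    ----------
    label:
        Leaf name, or raw internal-node label as parsed.
    length:
        Branch length to the parent, ``None`` when absent (absent is not 0).
    children:
        Child nodes (empty for leaves). Polytomies are first-class.
    supports:
        Ordered ``[(method, value)]`` support entries; ``value`` may be
        ``None`` for a method without support on this branch.
    """

    __slots__ = ("label", "length", "children", "parent", "supports")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        children: Optional[list["TreeNode"]] = None,
        supports: Optional[list[tuple[Optional[str], Optional[float]]]] = None,
    ):
        self.label = label
        self.length = length
        self.children: list[TreeNode] = children or []
        self.parent: Optional[TreeNode] = None
        self.supports = supports
        for c in self.children:
            c.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self) -> Iterator["TreeNode"]:
        stack: list[tuple[TreeNode, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "TreeNode":
        mapping: dict[int, TreeNode] = {}
        for node in self.postorder():
            clone = TreeNode(
                node.label,
                node.length,
                [mapping[id(c)] for c in node.children],
                None if node.supports is None else list(node.supports),
            )
            mapping[id(node)] = clone
        return mapping[id(self)]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"{len(self.children)} children"
        return f"<TreeNode {self.label!r} ({kind})>"


class Tree:
    """A phylogeny with a designated root and a rootedness flag.

    An unrooted topology is represented with ``is_rooted=False`` and a
    root of degree ≥ 3 (the usual trifurcation for binary unrooted trees).
    Leaf labels must be unique and non-empty.
    """

    def __init__(self, root: TreeNode, is_rooted: bool = True):
        if root is None:
            raise ValueError("tree must have a root node")
        self.root = root
        self.is_rooted = is_rooted
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for leaf in self.root.leaves():
            if not leaf.label:
                raise ValueError("leaf with empty label")
            if leaf.label in seen:
                raise ValueError(f"duplicate leaf label: {leaf.label!r}")
            seen.add(leaf.label)
        for node in self.root.postorder():
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length on {node.label!r}")

    # -- basic queries -------------------------------------------------

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaf_labels())

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def find_leaf(self, label: str) -> TreeNode:
        for leaf in self.leaves():
            if leaf.label == label:
                return leaf
        raise KeyError(label)

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), self.is_rooted)

    def __len__(self) -> int:
        return len(self.leaves())

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree with {len(self)} leaves, rooted={self.is_rooted}>"


class Bipartition:
    """A two-block partition of the leaf set induced by an internal edge.

    Canonically oriented: ``inside`` is the block that does *not* contain
    the reference leaf (lexicographically smallest label).
    """

    __slots__ = ("inside", "outside")

    def __init__(self, block: Iterable[str], all_leaves: Iterable[str]):
        all_set = frozenset(all_leaves)
        block = frozenset(block)
        if not block or block == all_set:
            raise ValueError("bipartition blocks must be non-empty")
        if not block <= all_set:
            raise ValueError("block is not a subset of the leaf set")
        ref = min(all_set)
        if ref in block:
            block = all_set - block
        self.inside = block
        self.outside = all_set - block

    @property
    def is_trivial(self) -> bool:
        return len(self.inside) == 1 or len(self.outside) == 1

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Bipartition)
            and self.inside == other.inside
            and self.outside == other.outside
        )

    def __hash__(self) -> int:
        return hash((self.inside, self.outside))

    def __repr__(self) -> str:  # pragma: no cover
        a = ",".join(sorted(self.inside))
        b = ",".join(sorted(self.outside))
        return f"{{{a}}}|{{{b}}}"


# ---------------------------------------------------------------------------
# Newick parsing


class _Parser:
    """Recursive-descent Newick reader.

    Dialect: quoted labels ('..', with '' escaping), scientific-notation
    branch lengths, bracketed comments (ignored), underscores kept verbatim.
    """

    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> NewickError:
        return NewickError(msg, self.pos)

    def _skip_ws_and_comments(self) -> None:
        while self.pos < len(self.text):
            ch = self.text[self.pos]
            if ch.isspace():
                self.pos += 1
            elif ch == "[":
                end = self.text.find("]", self.pos)
                if end < 0:
                    raise self.error("unterminated comment")
                self.pos = end + 1
            else:
                return

    def peek(self) -> str:
        self._skip_ws_and_comments()
        if self.pos >= len(self.text):
            raise self.error("unexpected end of input")
        return self.text[self.pos]

    def parse(self) -> TreeNode:
        self._skip_ws_and_comments()
        if self.pos >= len(self.text):
            raise self.error("empty Newick string")
        node = self._parse_node()
        self._skip_ws_and_comments()
        if self.pos >= len(self.text) or self.text[self.pos] != ";":
            raise self.error("expected ';' terminating the tree")
        return node

    def _parse_node(self) -> TreeNode:
        node = TreeNode()
        if self.peek() == "(":
            self.pos += 1
            while True:
                node.add_child(self._parse_node())
                ch = self.peek()
                if ch == ",":
                    self.pos += 1
                    continue
                if ch == ")":
                    self.pos += 1
                    break
                raise self.error(f"expected ',' or ')', found {ch!r}")
        label = self._parse_label()
        if label:
            node.label = label
            if node.children:
                node.supports = _supports_from_label(label)
        self._skip_ws_and_comments()
        if self.pos < len(self.text) and self.text[self.pos] == ":":
            self.pos += 1
            node.length = self._parse_length()
        if node.is_leaf and not node.label:
            raise self.error("leaf without a label")
        return node

    def _parse_label(self) -> Optional[str]:
        self._skip_ws_and_comments()
        if self.pos >= len(self.text):
            return None
        ch = self.text[self.pos]
        if ch == "'":
            return self._parse_quoted()
        out = []
        while self.pos < len(self.text):
            ch = self.text[self.pos]
            if ch in "():,;[" or ch.isspace():
                break
            out.append(ch)
            self.pos += 1
        return "".join(out) or None

    def _parse_quoted(self) -> str:
        assert self.text[self.pos] == "'"
        self.pos += 1
        out = []
        while True:
            if self.pos >= len(self.text):
                raise self.error("unterminated quoted label")
            ch = self.text[self.pos]
            if ch == "'":
                if self.pos + 1 < len(self.text) and self.text[self.pos + 1] == "'":
                    out.append("'")
                    self.pos += 2
                    continue
                self.pos += 1
                break
            out.append(ch)
            self.pos += 1
        return "".join(out)

    def _parse_length(self) -> float:
        self._skip_ws_and_comments()
        m = _FLOAT_RE.match(self.text, self.pos)
        if not m:
            raise self.error("expected a branch length after ':'")
        self.pos = m.end()
        return float(m.group())


def _supports_from_label(
    label: str,
) -> Optional[list[tuple[Optional[str], Optional[float]]]]:
    """Interpret an internal-node label as support annotation, if it is one.

    A slash-separated triplet maps onto the canonical ML/NJ/MP order; a bare
    number becomes a single anonymous support entry.
    """
    parts = label.split("/")
    values: list[Optional[float]] = []
    for part in parts:
        part = part.strip()
        if part == "-" or part == "":
            values.append(None)
        else:
            try:
                values.append(float(part))
            except ValueError:
                return None
    if len(parts) == 1:
        return [(None, values[0])] if values[0] is not None else None
    methods: Sequence[Optional[str]]
    if len(values) == len(METHOD_ORDER):
        methods = METHOD_ORDER
    else:
        methods = [None] * len(values)
    return list(zip(methods, values))


def parse_newick(text: str) -> Tree:
    """Parse one Newick tree from ``text``.

    Raises :class:`NewickError` naming the offending position for malformed
    input, and ``ValueError`` for duplicate leaf labels.
    """
    root = _Parser(text).parse()
    is_rooted = len(root.children) <= 2
    return Tree(root, is_rooted=is_rooted)


def _format_label(label: str) -> str:
    if _NEEDS_QUOTE_RE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_length(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


def _support_label(node: TreeNode) -> Optional[str]:
    if node.supports is not None:
        parts = []
        for _method, value in node.supports:
            if value is None:
                parts.append("-")
            elif value == int(value):
                parts.append(str(int(value)))
            else:
                parts.append(f"{value:g}")
        return "/".join(parts)
    return node.label


def write_newick(tree: Tree) -> str:
    """Serialize a tree to Newick; the result reparses to an equal tree."""
    if tree.root is None or (tree.root.is_leaf and not tree.root.label):
        raise ValueError("cannot serialize an empty tree")

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            s = _format_label(node.label)
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            label = _support_label(node)
            if label:
                s += _format_label(label)
        if node.length is not None:
            s += ":" + _format_length(node.length)
        return s

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Bipartitions


def bipartitions(tree: Tree) -> set[Bipartition]:
    """Nontrivial bipartitions of the (unrooted) topology, one per internal edge.

    Invariant under re-rooting; trivial splits (singleton block) excluded.
    """
    all_leaves = tree.leaf_set()
    if len(all_leaves) < 4:
        return set()
    out: set[Bipartition] = set()
    leafsets: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            leafsets[id(node)] = frozenset([node.label])
        else:
            leafsets[id(node)] = frozenset().union(
                *(leafsets[id(c)] for c in node.children)
            )
    for node in tree.postorder():
        if node is tree.root or node.is_leaf:
            continue
        block = leafsets[id(node)]
        if 1 < len(block) < len(all_leaves) - 1:
            out.add(Bipartition(block, all_leaves))
    return out


# ---------------------------------------------------------------------------
# Rooting


def _adjacency(
    tree: Tree,
) -> dict[int, list[tuple[TreeNode, float]]]:
    """Undirected adjacency with edge lengths; errors on missing lengths."""
    adj: dict[int, list[tuple[TreeNode, float]]] = {}
    for node in tree.postorder():
        adj.setdefault(id(node), [])
        for c in node.children:
            if c.length is None:
                raise ValueError(
                    f"branch length missing on edge above {c.label or 'internal node'}"
                )
            adj[id(node)].append((c, c.length))
            adj.setdefault(id(c), []).append((node, c.length))
    return adj


def _farthest(
    start: TreeNode, adj: dict[int, list[tuple[TreeNode, float]]]
) -> tuple[TreeNode, float, dict[int, tuple[Optional[TreeNode], float]]]:
    """Farthest *leaf* from start, with back-pointers for path recovery."""
    back: dict[int, tuple[Optional[TreeNode], float]] = {id(start): (None, 0.0)}
    best, best_d = start, 0.0
    stack = [(start, 0.0)]
    while stack:
        node, d = stack.pop()
        if node.is_leaf and d > best_d:
            best, best_d = node, d
        for nbr, w in adj[id(node)]:
            if id(nbr) not in back:
                back[id(nbr)] = (node, w)
                stack.append((nbr, d + w))
    return best, best_d, back


def _reroot_at(child: TreeNode, dist_below_parent: float) -> Tree:
    """Re-root the tree on the edge above ``child``.

    The new root sits on that edge, ``dist_below_parent`` below the parent
    endpoint. Degree-2 relic nodes are spliced out.
    """
    edge_len = child.length
    if edge_len is None:
        raise ValueError("cannot reroot on an edge without a length")
    parent = child.parent
    assert parent is not None
    new_root = TreeNode()
    # Detach child
    parent.children.remove(child)
    child.parent = None
    child.length = edge_len - dist_below_parent
    # Reverse the path parent -> ... -> old root
    path = []
    node = parent
    while node is not None:
        path.append(node)
        node = node.parent
    # Reverse parent pointers: each node on the path becomes a child of its
    # former child; branch lengths shift accordingly.
    lengths = [n.length for n in path]
    for i, node in enumerate(path):
        if i + 1 < len(path):
            path[i + 1].children.remove(node)
        node.parent = None
    for i in range(len(path) - 1):
        node, nxt = path[i], path[i + 1]
        node.add_child(nxt)
        nxt.length = lengths[i]
    new_root.add_child(child)
    new_root.add_child(parent)
    parent.length = dist_below_parent
    # Splice out degree-2 nodes left behind (old root had >=2 children; after
    # reversal it keeps children-1).
    _splice_unifurcations(new_root)
    out = Tree(new_root, is_rooted=True)
    return out


def _splice_unifurcations(root: TreeNode) -> None:
    for node in list(root.postorder()):
        if node is root or node.is_leaf:
            continue
        if len(node.children) == 1:
            child = node.children[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = child
            child.parent = parent
    if len(root.children) == 1:
        only = root.children[0]
        if not only.is_leaf:
            grand = only.children
            root.children = grand
            for g in grand:
                g.parent = root
                if only.length:
                    g.length = (g.length or 0.0) + only.length


def midpoint_root(tree: Tree, tol: float = 1e-9) -> Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Requires branch lengths on all edges; idempotent and path-length
    preserving up to ``tol``.
    """
    work = tree.copy()
    leaves = work.leaves()
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least two leaves")
    adj = _adjacency(work)
    u, _, _ = _farthest(leaves[0], adj)
    v, diameter, back = _farthest(u, adj)
    half = diameter / 2.0
    # Walk back from v toward u accumulating distance until we pass `half`
    # measured from u; equivalently (diameter - half) from v.
    target_from_v = diameter - half
    node = v
    walked = 0.0
    while True:
        prev, w = back[id(node)]
        if prev is None:
            raise RuntimeError("midpoint walk escaped the u-v path")
        if walked + w >= target_from_v - tol:
            break
        walked += w
        node = prev
    # Midpoint lies on the edge between `node` and `prev`, at
    # (target_from_v - walked) from `node` toward `prev`.
    offset = min(max(target_from_v - walked, 0.0), w)
    if node.parent is prev:
        return _reroot_at(node, w - offset)
    else:
        assert prev.parent is node
        return _reroot_at(prev, offset)


def root_by_split(tree: Tree, split: Iterable[str]) -> Tree:
    """Re-root (topologically) at the edge best matching a leaf-label split.

    Used to carry a reference rooting onto a re-estimated tree: the edge
    whose induced bipartition has the smallest symmetric difference to
    ``split`` (or its complement) becomes the root edge. Branch lengths
    are not required; the root is placed at the midpoint when the edge
    has a length, at an unlengthed point otherwise.
    """
    split = frozenset(split)
    work = tree.copy()
    all_leaves = work.leaf_set()
    target = None
    target_score = None
    leafsets: dict[int, frozenset[str]] = {}
    for node in work.postorder():
        if node.is_leaf:
            leafsets[id(node)] = frozenset([node.label])
        else:
            leafsets[id(node)] = frozenset().union(
                *(leafsets[id(c)] for c in node.children)
            )
        if node is work.root:
            continue
        blk = leafsets[id(node)]
        score = min(
            len(blk.symmetric_difference(split)),
            len(blk.symmetric_difference(all_leaves - split)),
        )
        if target_score is None or score < target_score:
            target, target_score = node, score
    if target is None or target.parent is None:
        return work
    if target.length is not None:
        return _reroot_at(target, target.length / 2.0)
    target.length = 1.0
    out = _reroot_at(target, 0.5)
    # Strip the synthetic lengths introduced for the split edge
    for child in out.root.children:
        if child.length == 0.5:
            child.length = None
    return out


def outgroup_root(tree: Tree, outgroup: Iterable[str]) -> Tree:
    """Root on the edge above the smallest clade containing the outgroup taxa.

    If the outgroup is not monophyletic in the current rooting, the edge
    above the MRCA of the outgroup taxa is used.
    """
    work = tree.copy()
    targets = set(outgroup)
    missing = targets - set(work.leaf_labels())
    if missing:
        raise ValueError(f"outgroup taxa not in tree: {sorted(missing)}")
    if not targets:
        raise ValueError("empty outgroup")
    leafsets: dict[int, frozenset[str]] = {}
    mrca = None
    for node in work.postorder():
        if node.is_leaf:
            leafsets[id(node)] = frozenset([node.label])
        else:
            leafsets[id(node)] = frozenset().union(
                *(leafsets[id(c)] for c in node.children)
            )
        if mrca is None and targets <= leafsets[id(node)]:
            mrca = node
    assert mrca is not None
    if mrca is work.root:
        # Outgroup spans the root; try the complement side of one outgroup leaf
        for node in work.postorder():
            if leafsets[id(node)] == frozenset(work.leaf_labels()) - targets:
                mrca = node
                break
        else:
            raise ValueError("outgroup is not monophyletic around the root")
    length = mrca.length if mrca.length is not None else 1.0
    if mrca.length is None:
        mrca.length = length  # synthesize a unit edge so the split is defined
    return _reroot_at(mrca, length / 2.0)


def leaf_path_lengths(tree: Tree) -> dict[str, float]:
    """Root-to-leaf path lengths (missing lengths treated as errors)."""
    out: dict[str, float] = {}
    depth: dict[int, float] = {id(tree.root): 0.0}
    for node in tree.preorder():
        if node is not tree.root:
            if node.length is None:
                raise ValueError("missing branch length")
            depth[id(node)] = depth[id(node.parent)] + node.length
        if node.is_leaf:
            out[node.label] = depth[id(node)]
    return out


def tree_from_bipartitions(
    leaf_labels: Iterable[str], biparts: Iterable[Bipartition]
) -> Tree:
    """Build the (possibly multifurcating) tree realizing a compatible split set.

    The splits must be pairwise compatible (as any subset of one tree's
    splits is); the result is rooted at a star node holding the reference
    leaf, with ``is_rooted=False`` since the topology is unrooted.
    """
    leaves = sorted(set(leaf_labels))
    blocks = sorted({bp.inside for bp in biparts}, key=len)
    for i, a in enumerate(blocks):
        for b in blocks[i + 1 :]:
            if a & b and not a <= b:
                raise ValueError("incompatible bipartitions")
    nodes: dict[frozenset[str], TreeNode] = {
        frozenset([lf]): TreeNode(label=lf) for lf in leaves
    }
    root = TreeNode()
    containers = blocks + [frozenset(leaves)]
    nodes_by_block = {blk: TreeNode() for blk in blocks}
    nodes_by_block[frozenset(leaves)] = root
    units = list(nodes.items()) + [
        (blk, nodes_by_block[blk]) for blk in blocks
    ]
    for key, node in units:
        parent_block = min(
            (blk for blk in containers if key < blk), key=len, default=None
        )
        if parent_block is None:
            root.add_child(node)
        else:
            nodes_by_block[parent_block].add_child(node)
    return Tree(root, is_rooted=False)


def pairwise_leaf_distances(tree: Tree) -> dict[tuple[str, str], float]:
    """All pairwise leaf-to-leaf path lengths (small trees; testing aid)."""
    adj = _adjacency(tree)
    leaves = tree.leaves()
    out: dict[tuple[str, str], float] = {}
    for src in leaves:
        dist = {id(src): 0.0}
        stack = [(src, 0.0)]
        while stack:
            node, d = stack.pop()
            for nbr, w in adj[id(node)]:
                if id(nbr) not in dist:
                    dist[id(nbr)] = d + w
                    stack.append((nbr, d + w))
        for dst in leaves:
            if src.label < dst.label:
                out[(src.label, dst.label)] = dist[id(dst)]
    return out
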