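"""Stage 4: strict-intersection combination of per-method trees.

The combined tree keeps exactly the bipartitions present in every input
tree — the strongest reading of "only branches supported by all methods" —
collapsing every contested edge into a polytomy. Each retained edge is
annotated with every method's bootstrap support, in the canonical ML/NJ/MP
order, so low-support but topologically shared branches survive with
their (possibly low) values visible.

A relaxed mode keeps bipartitions shared by at least ``min_methods`` of
the inputs (e.g. 2 of 3), for sensitivity analysis; the relaxed split set
can contain incompatible splits only if the shared ones conflict, which
cannot happen for splits drawn from trees over one leaf set when
``min_methods`` exceeds half the inputs.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .trees import (
    METHOD_ORDER,
    Bipartition,
    Tree,
    bipartitions,
    tree_from_bipartitions,
)

__all__ = ["combine_method_trees", "support_table"]


def _method_sort_key(name: str) -> tuple[int, str]:
    upper = name.upper()
    if upper in METHOD_ORDER:
        return (METHOD_ORDER.index(upper), upper)
    return (len(METHOD_ORDER), upper)


def _node_support(tree: Tree, wanted: Bipartition) -> Optional[float]:
    """The support annotated on the edge inducing ``wanted`` in ``tree``."""
    leafset = tree.leaf_set()
    blocks: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            blocks[id(node)] = frozenset([node.label])
            continue
        blocks[id(node)] = frozenset().union(*(blocks[id(c)] for c in node.children))
        if node is tree.root:
            continue
        blk = blocks[id(node)]
        if 1 < len(blk) < len(leafset) - 1 and Bipartition(blk, leafset) == wanted:
            if node.supports:
                values = [v for _m, v in node.supports if v is not None]
                if values:
                    return values[0]
            if node.label:
                try:
                    return float(node.label)
                except ValueError:
                    return None
            return None
    return None


def combine_method_trees(
    trees: Sequence[tuple[str, Tree]],
    min_methods: Optional[int] = None,
) -> Tree:
    """Combine ≥ 2 method trees over one leaf set into a consensus topology.

    By default (strict mode) the result contains exactly the bipartitions
    present in *all* inputs; ``min_methods`` relaxes this to a
    majority-style rule. Branch lengths are dropped (methods' lengths are
    incommensurable); every retained edge carries the ordered support list
    of all methods.
    """
    if len(trees) < 2:
        raise ValueError("combination needs at least two method trees")
    names = [name for name, _ in trees]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate method names: {names}")
    leafsets = [t.leaf_set() for _, t in trees]
    base = leafsets[0]
    for (name, _), ls in zip(trees[1:], leafsets[1:]):
        if ls != base:
            diff = sorted(base.symmetric_difference(ls))
            raise ValueError(
                f"leaf sets differ between {names[0]!r} and {name!r}: {diff}"
            )
    required = len(trees) if min_methods is None else min_methods
    if not (1 <= required <= len(trees)):
        raise ValueError("min_methods out of range")
    if 2 * required <= len(trees):
        raise ValueError("min_methods must exceed half the inputs")

    split_sets = {name: bipartitions(t) for name, t in trees}
    tally: dict[Bipartition, int] = {}
    for splits in split_sets.values():
        for bp in splits:
            tally[bp] = tally.get(bp, 0) + 1
    kept = {bp for bp, c in tally.items() if c >= required}

    combined = tree_from_bipartitions(base, kept)

    # Annotate each retained edge with every method's support.
    order = sorted(names, key=_method_sort_key)
    support_cache = {
        (name, bp): _node_support(dict(trees)[name], bp)
        for name in names
        for bp in kept
        if bp in split_sets[name]
    }
    blocks: dict[int, frozenset[str]] = {}
    for node in combined.postorder():
        if node.is_leaf:
            blocks[id(node)] = frozenset([node.label])
            continue
        blocks[id(node)] = frozenset().union(*(blocks[id(c)] for c in node.children))
        if node is combined.root:
            continue
        blk = blocks[id(node)]
        if not (1 < len(blk) < len(base) - 1):
            continue
        bp = Bipartition(blk, base)
        node.supports = [
            (name, support_cache.get((name, bp))) for name in order
        ]
    return combined


def support_table(
    combined: Tree,
) -> list[dict[str, object]]:
    """Tabulate bipartition × method support of a combined tree."""
    base = combined.leaf_set()
    rows: list[dict[str, object]] = []
    blocks: dict[int, frozenset[str]] = {}
    for node in combined.postorder():
        if node.is_leaf:
            blocks[id(node)] = frozenset([node.label])
            continue
        blocks[id(node)] = frozenset().union(*(blocks[id(c)] for c in node.children))
        if node is combined.root or not node.supports:
            continue
        blk = blocks[id(node)]
        if not (1 < len(blk) < len(base) - 1):
            continue
        row: dict[str, object] = {"bipartition": "|".join(sorted(blk))}
        for method, value in node.supports:
            row[method or "support"] = value
        rows.append(row)
    return rows
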