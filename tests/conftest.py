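import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hgtscan.trees import Tree, TreeNode

settings.register_profile(
    "ci",
    database=None,
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_tree(labels, rng, min_len=0.1, max_len=1.0):
    """Random binary rooted tree over ``labels`` with positive lengths."""
    nodes = [TreeNode(label=lb) for lb in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(TreeNode(children=[a, b]))
    tree = Tree(nodes[0], is_rooted=True)
    for node in tree.postorder():
        if node is not tree.root:
            node.length = float(rng.uniform(min_len, max_len))
    return tree


def all_unrooted_topologies(labels):
    """Every unrooted binary topology over ``labels`` ((2n-5)!! trees).

    Built by inserting taxa one at a time into every edge — the brute-force
    oracle for heuristic tree searches.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least three labels")
    base = Tree(
        TreeNode(children=[TreeNode(label=lb) for lb in labels[:3]]),
        is_rooted=False,
    )
    trees = [base]
    for lb in labels[3:]:
        nxt = []
        for t in trees:
            edges = [
                (node, child)
                for node in t.postorder()
                for child in node.children
            ]
            for i in range(len(edges)):
                t2 = t.copy()
                edges2 = [
                    (node, child)
                    for node in t2.postorder()
                    for child in node.children
                ]
                parent, child = edges2[i]
                mid = TreeNode(children=[TreeNode(label=lb)])
                idx = parent.children.index(child)
                parent.children[idx] = mid
                mid.parent = parent
                mid.add_child(child)
                nxt.append(Tree(t2.root, is_rooted=False))
        trees = nxt
    return trees


def random_protein_alignment(ids, length, rng, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    from hgtscan.alignment import Alignment

    rows = tuple(
        "".join(rng.choice(list(alphabet), size=length)) for _ in ids
    )
    return Alignment(tuple(ids), rows)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def quartet_tree():
    from hgtscan.trees import parse_newick

    return parse_newick("((A:1,B:2):1,(C:3,D:4):1);")


@pytest.fixture
def five_leaf_kingdoms():
    return {
        "b1": "Bacteria",
        "b2": "Bacteria",
        "b3": "Bacteria",
        "b4": "Bacteria",
        "p1": "Plantae",
    }
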