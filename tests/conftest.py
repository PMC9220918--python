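import numpy as np
import pytest
from skbio import TreeNode

from rarephylo.io import CommunityTable


@pytest.fixture
def balanced_tree() -> TreeNode:
    """((A:1,B:1):1,(C:1,D:1):1): the hand-computable reference tree."""
    return TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1):0;"])


@pytest.fixture
def star_tree() -> TreeNode:
    return TreeNode.read(["(A:1,B:1,C:1,D:1):0;"])


@pytest.fixture
def toy_table() -> CommunityTable:
    counts = np.array(
        [
            [10, 0, 5, 1],
            [5, 5, 5, 0],
            [8, 2, 0, 3],
        ]
    )
    return CommunityTable(counts, ["S1", "S2", "S3"], ["A", "B", "C", "D"])


def random_tree(n_tips: int, rng: np.random.Generator) -> TreeNode:
    """Random rooted binary tree with uniform random branch lengths in (0, 1]."""
    nodes = [TreeNode(name=f"T{i}", length=None) for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b])
        nodes.append(parent)
    root = nodes[0]
    for node in root.traverse(include_self=False):
        node.length = float(rng.uniform(0.05, 1.0))
    root.length = None
    return root
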