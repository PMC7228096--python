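import random

import pytest

from rootbench.trees import RootedTree, TreeNode, unroot


def random_rooted_tree(n_leaves, rng, length_range=(0.1, 1.0), labels=None):
    """Uniform-ish random binary rooted tree built by repeated joining."""
    if labels is None:
        labels = [f"L{i}" for i in range(n_leaves)]
    nodes = [TreeNode(lab, rng.uniform(*length_range)) for lab in labels]
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        parent = TreeNode(None, rng.uniform(*length_range))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    nodes[0].length = 0.0
    return RootedTree(nodes[0])


def random_unrooted_tree(n_leaves, rng, length_range=(0.1, 1.0), labels=None):
    return unroot(random_rooted_tree(n_leaves, rng, length_range, labels))


@pytest.fixture
def rng():
    return random.Random(20260920)
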