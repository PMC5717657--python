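import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20170899)


@pytest.fixture
def small_chronogram():
    """Fixed dated 4-tip tree: ((A:1,B:3):2,(C:4,D:1):3); root age 5."""
    from disparitree import build_tree

    tree = build_tree((("A", "B"), ("C", "D")))
    root = tree.root
    root.age = 5.0
    left, right = root.children
    left.age = 3.0
    right.age = 4.0
    a, b = left.children
    a.age, b.age = 2.0, 0.0
    c, d = right.children
    c.age, d.age = 0.0, 3.0
    return tree


def random_chronogram(rng, n_tips, max_depth=10.0):
    """Random binary dated tree by recursive age subdivision."""
    from disparitree.trees import Node, Tree

    labels = [f"t{i}" for i in range(n_tips)]
    nodes = [Node(lbl, age=float(rng.uniform(0, max_depth / 4)))
             for lbl in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = Node(age=max(a.age, b.age) + float(rng.uniform(0.1, max_depth / n_tips)))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    return Tree(nodes[0])
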