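"""Independent reference implementations used as test oracles.

Everything here is written directly from the contracts, without reusing
the package's algorithm code, so agreement is a genuine cross-check.
"""

import itertools

import numpy as np

from disparitree.trees import Node, Tree


# ----------------------------------------------------------------------
# naive three-stage 'equal' time-scaling on a nested-dict tree
# ----------------------------------------------------------------------

def equal_scale_reference(tree, tip_ages, constraints=(), vartime=1.0):
    """Direct recursive implementation of the three-stage procedure.

    Works on a copy of a :class:`disparitree.trees.Tree`; returns a map
    node-path -> age, where a node's path is the sorted tuple of tip
    labels below it (unique per node in the trees we enumerate only if
    no two nodes subtend the same tip set, i.e. no unifurcations).
    """
    tree = tree.copy()

    # stage 1: oldest descendant tip age, raised by constraint minima
    def tipset(node):
        if node.is_leaf:
            return frozenset([node.label])
        return frozenset().union(*(tipset(c) for c in node.children))

    # constraint -> MRCA tipset: smallest clade containing the tips
    mins = {}
    all_nodes = list(tree.preorder())
    for tips, min_age in constraints:
        tips = frozenset(tips)
        candidates = [n for n in all_nodes if tipset(n) >= tips]
        mrca = min(candidates, key=lambda n: len(tipset(n)))
        mins[id(mrca)] = max(mins.get(id(mrca), 0.0), min_age)

    def stage1(node):
        if node.is_leaf:
            node.age = float(tip_ages[node.label])
        else:
            for c in node.children:
                stage1(c)
            node.age = max(c.age for c in node.children)
            if id(node) in mins:
                node.age = max(node.age, mins[id(node)])

    stage1(tree.root)

    # stage 2
    tree.root.age += vartime

    # stage 3: per maximal zero chain (deepest first), evenly respace
    # the path from the nearest positive ancestral branch
    def depth(node):
        d = 0
        while node.parent is not None:
            d += 1
            node = node.parent
        return d

    while True:
        zeros = [n for n in tree.preorder()
                 if n.parent is not None and n.parent.age - n.age <= 1e-12]
        if not zeros:
            break
        bottom = max(zeros, key=lambda n: (depth(n),
                                           -[id(m) for m in tree.preorder()].index(id(n))))
        # path of nodes with equal age, walking up to the donor branch
        path = [bottom]
        while path[-1].parent.parent is not None and \
                path[-1].parent.parent.age - path[-1].parent.age <= 1e-12:
            path.append(path[-1].parent)
        top = path[-1].parent               # top node of the equal-age run
        donor_parent_age = top.parent.age   # must exist and be older
        ages = np.linspace(donor_parent_age, bottom.age, len(path) + 2)
        movers = [top] + path[::-1][:-1]  # bottom keeps its age
        for node, age in zip(movers, ages[1:-1]):
            node.age = float(age)

    return {tuple(sorted(tipset(n))): n.age for n in tree.preorder()}


# ----------------------------------------------------------------------
# enumeration of all rooted binary labelled topologies
# ----------------------------------------------------------------------

def all_rooted_binary_topologies(labels):
    """Yield nested-tuple shapes for every rooted binary labelled tree.

    Counts follow (2n-3)!!: 1, 1, 3, 15, 105 for n = 1..5.
    """
    labels = list(labels)
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    for r in range(len(rest)):
        for left_rest in itertools.combinations(rest, r):
            left = [first, *left_rest]
            right = [x for x in rest if x not in left_rest]
            if not right:
                continue
            for lt in all_rooted_binary_topologies(left):
                for rt in all_rooted_binary_topologies(right):
                    yield (lt, rt)


def as_tree(shape):
    """Nested-tuple shape -> Tree."""
    def rec(s):
        if isinstance(s, str):
            return Node(label=s)
        node = Node()
        for child in s:
            node.add_child(rec(child))
        return node

    return Tree(rec(shape))


# ----------------------------------------------------------------------
# brute-force minimiser of the squared-change objective
# ----------------------------------------------------------------------

def squared_change_minimizer(tree, tip_traits):
    """Solve min sum (x_child - x_parent)^2 / v directly.

    The objective is quadratic, so the unique minimiser satisfies the
    weighted-graph normal equations L_II x_I = -L_IB x_B built here from
    scratch (L = Laplacian of the tree with edge weights 1/v).
    """
    nodes = list(tree.preorder())
    idx = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    L = np.zeros((n, n))
    for node in nodes:
        if node.parent is None:
            continue
        w = 1.0 / max(node.parent.age - node.age, 1e-8)
        i, j = idx[id(node)], idx[id(node.parent)]
        L[i, i] += w
        L[j, j] += w
        L[i, j] -= w
        L[j, i] -= w
    internal = [i for i, nd in enumerate(nodes) if not nd.is_leaf]
    tips = [i for i, nd in enumerate(nodes) if nd.is_leaf]
    xB = np.stack([np.atleast_1d(np.asarray(tip_traits[nodes[i].label],
                                            dtype=float)) for i in tips])
    LII = L[np.ix_(internal, internal)]
    LIB = L[np.ix_(internal, tips)]
    xI = np.linalg.solve(LII, -LIB @ xB)
    return {id(nodes[i]): xI[k] for k, i in enumerate(internal)}


# ----------------------------------------------------------------------
# brute-force slice at time t
# ----------------------------------------------------------------------

def slice_reference(tree, t):
    """All-branch scan with closed-interval membership and node dedup."""
    samples = {}
    if t == tree.root.age:
        samples[("node", id(tree.root))] = np.atleast_1d(tree.root.traits)
    for node in tree.preorder():
        if node.parent is None:
            continue
        a_c, a_p = node.age, node.parent.age
        if not (a_c <= t <= a_p):
            continue
        x_c = np.atleast_1d(node.traits)
        x_p = np.atleast_1d(node.parent.traits)
        value = x_p + (x_c - x_p) * (a_p - t) / (a_p - a_c)
        if t == a_c:
            key = ("node", id(node))
        elif t == a_p:
            key = ("node", id(node.parent))
        else:
            key = ("branch", id(node))
        samples[key] = value
    return list(samples.values())
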