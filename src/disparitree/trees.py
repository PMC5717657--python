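"""Rooted-tree container used throughout the package.

A single lightweight :class:`Tree` serves both roles the pipeline needs:

* a *topology* — rooted, possibly polytomous, ages unset;
* a *chronogram* — every node carries an ``age`` in Ma before present
  (larger = older), so a branch's duration is ``parent.age - child.age``
  in Myr.

Trait vectors (PC scores) attach to nodes via ``node.traits``.  Parsing
and serialisation of Newick/NEXUS go through dendropy; the algorithms in
this package operate on this container directly.
"""

from __future__ import annotations

from typing import Callable, Iterable, Iterator, Optional, Sequence

import dendropy
import numpy as np

__all__ = ["Node", "Tree", "InputError"]


class InputError(ValueError):
    """Raised when user-supplied data violates a documented precondition."""


class Node:
    """A node of a rooted tree.

    Attributes
    ----------
    label : str or None
        Tip label (unique within a tree) or optional internal-node label.
    children : list of Node
    parent : Node or None
    age : float or None
        Ma before present; ``None`` on bare topologies.
    length : float or None
        Edge length above this node, used only when a tree is read from a
        file with branch lengths and no ages.
    traits : numpy.ndarray or None
        p-vector of trait values (observed at tips, estimated at internal
        nodes).
    """

    __slots__ = ("label", "children", "parent", "age", "length", "traits")

    def __init__(self, label: Optional[str] = None, age: Optional[float] = None,
                 length: Optional[float] = None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.age = age
        self.length = length
        self.traits: Optional[np.ndarray] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} age={self.age}>"


class Tree:
    """Rooted tree; see module docstring for the two roles it plays."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------
    # traversal
    # ------------------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    def find_tip(self, label: str) -> Node:
        for t in self.tips():
            if t.label == label:
                return t
        raise InputError(f"unknown tip {label!r}")

    # ------------------------------------------------------------------
    # structure queries
    # ------------------------------------------------------------------
    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def clades(self) -> set[frozenset]:
        """Tip-label set of every internal node (including the root)."""
        below: dict[int, frozenset] = {}
        out: set[frozenset] = set()
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                cl = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = cl
                out.add(cl)
        return out

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of a set of tip labels."""
        want = set(labels)
        known = set(self.tip_labels)
        missing = want - known
        if missing:
            raise InputError(f"unknown tips in MRCA query: {sorted(missing)}")
        if not want:
            raise InputError("empty tip set in MRCA query")
        below: dict[int, set] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = {node.label} & want
            else:
                below[id(node)] = set().union(*(below[id(c)] for c in node.children))
            if below[id(node)] >= want:
                return node
        raise AssertionError("unreachable: root covers all tips")

    def duration(self, node: Node) -> float:
        """Branch duration above ``node`` in Myr (requires ages)."""
        if node.is_root:
            raise ValueError("root has no branch above it")
        return node.parent.age - node.age

    # ------------------------------------------------------------------
    # copying / editing
    # ------------------------------------------------------------------
    def copy(self) -> "Tree":
        def rec(node: Node) -> Node:
            new = Node(node.label, node.age, node.length)
            if node.traits is not None:
                new.traits = node.traits.copy()
            for c in node.children:
                new.add_child(rec(c))
            return new

        return Tree(rec(self.root))

    def prune_to(self, keep: Iterable[str]) -> "Tree":
        """Restrict to a tip subset, suppressing unifurcations.

        Edge lengths (``length``) of suppressed degree-2 nodes are summed;
        ages, where present, are carried over unchanged so path lengths to
        the retained tips are preserved automatically.
        """
        keep = set(keep)
        known = set(self.tip_labels)
        if not keep <= known:
            raise InputError(f"unknown tips: {sorted(keep - known)}")
        if len(keep) < 2:
            raise InputError("need at least 2 tips to prune to")

        tree = self.copy()

        def rec(node: Node) -> Optional[Node]:
            if node.is_leaf:
                return node if node.label in keep else None
            kids = [rec(c) for c in node.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                child = kids[0]
                # suppress this degree-2 node: child absorbs its edge
                if child.length is not None and node.length is not None:
                    child.length = child.length + node.length
                elif node.length is not None and child.length is None:
                    child.length = node.length
                child.parent = None
                return child
            node.children = []
            for k in kids:
                node.add_child(k)
            return node

        new_root = rec(tree.root)
        if new_root is None:
            raise InputError("no tips retained")
        new_root.parent = None
        return Tree(new_root)

    # ------------------------------------------------------------------
    # dendropy bridge
    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Tree":
        def rec(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = Node(label=label, length=dnode.edge.length)
            for dchild in dnode.child_nodes():
                node.add_child(rec(dchild))
            return node

        return cls(rec(dtree.seed_node))

    def to_dendropy(self, with_ages_as_comments: bool = False) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)

        def rec(node: Node, dnode) -> None:
            if node.is_leaf:
                dnode.taxon = taxa.require_taxon(label=node.label)
            elif node.label:
                dnode.label = node.label
            if node.age is not None and node.parent is not None:
                dnode.edge.length = node.parent.age - node.age
            elif node.length is not None:
                dnode.edge.length = node.length
            if with_ages_as_comments and node.age is not None:
                dnode.annotations.add_new("age", round(node.age, 9))
            for c in node.children:
                rec(c, dnode.new_child())

        rec(self.root, dtree.seed_node)
        return dtree

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  suppress_internal_node_taxa=True)
        return cls.from_dendropy(dtree)

    def to_newick(self, **kwargs) -> str:
        dtree = self.to_dendropy(**kwargs)
        return dtree.as_string(schema="newick",
                               suppress_annotations=False,
                               suppress_rooting=True).strip()

    # ------------------------------------------------------------------
    # age helpers
    # ------------------------------------------------------------------
    def set_ages_from_lengths(self, tip_ages: Optional[dict] = None) -> None:
        """Derive node ages from edge ``length`` values.

        Depths accumulate from the root; the maximum root-to-tip depth
        anchors age zero unless ``tip_ages`` pins specific tips.
        """
        depth: dict[int, float] = {id(self.root): 0.0}
        for node in self.preorder():
            if node.is_root:
                continue
            if node.length is None:
                raise InputError(f"node {node.label!r} has no branch length")
            depth[id(node)] = depth[id(node.parent)] + node.length
        if tip_ages:
            # anchor so that each tip's age matches; use the first tip
            tip = self.find_tip(next(iter(tip_ages)))
            root_age = tip_ages[tip.label] + depth[id(tip)]
        else:
            root_age = max(depth[id(t)] for t in self.tips())
        for node in self.preorder():
            node.age = root_age - depth[id(node)]

    def validate_chronogram(self, tol: float = 1e-9) -> None:
        for node in self.preorder():
            if node.age is None:
                raise InputError(f"node {node.label!r} has no age")
            if not node.is_root and node.parent.age - node.age <= -tol:
                raise InputError(
                    f"negative branch duration above {node.label!r}")

    def assign_internal_labels(self, prefix: str = "nd") -> None:
        """Give every unlabelled internal node a stable preorder label."""
        i = 0
        for node in self.preorder():
            if not node.is_leaf and not node.label:
                node.label = f"{prefix}{i}"
            if not node.is_leaf:
                i += 1


def build_tree(spec: Sequence, ages: Optional[dict] = None) -> Tree:
    """Build a tree from a nested-tuple description (testing convenience).

    ``spec`` is either a tip label (str) or a sequence of child specs.
    ``ages`` maps labels to ages for tips; internal nodes stay unaged.
    """

    def rec(s) -> Node:
        if isinstance(s, str):
            node = Node(label=s)
            if ages and s in ages:
                node.age = ages[s]
            return node
        node = Node()
        for child in s:
            node.add_child(rec(child))
        return node

    return Tree(rec(spec))
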