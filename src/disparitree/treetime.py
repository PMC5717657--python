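"""Stochastic time-scaling of a supertree with fossil tips.

Fossil-bearing supertrees come without branch durations: tips carry
stratigraphic age *ranges*, internal nodes at best minimum-age
constraints from molecular-clock studies, and many nodes are unresolved
polytomies.  This module turns one such topology into an ensemble of
dated trees by repeating, per replicate:

1. optionally resolving polytomies at random,
2. drawing each fossil tip's age (oldest bound, or uniformly within its
   stratigraphic range; extant tips are fixed at 0 Ma),
3. drawing one node-constraint set from a collection (emulating a sample
   of posterior clock trees), and
4. applying the three-stage 'equal' dating procedure: node ages start at
   the oldest descendant age (raised to any applicable constraint
   minimum), the root is pushed back by a fixed ``vartime`` term, and
   zero-duration branches then receive time by evenly redistributing the
   duration of the nearest ancestral positive branch along the chain.

Ages are Ma before present (larger = older); durations are Myr.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .trees import InputError, Node, Tree

__all__ = [
    "StratRange",
    "NodeConstraint",
    "TimeScaleSpec",
    "resolve_polytomies_random",
    "sample_fossil_ages",
    "time_scale_equal",
    "build_tree_set",
]

_ZERO = 1e-12


@dataclass(frozen=True)
class StratRange:
    """Stratigraphic age range of one tip: [younger_bound, older_bound] Ma.

    Extant tips have both bounds equal to zero.
    """

    tip_id: str
    older_bound: float
    younger_bound: float

    def __post_init__(self):
        if self.younger_bound < 0 or self.older_bound < self.younger_bound:
            raise InputError(
                f"invalid range for {self.tip_id!r}: "
                f"older={self.older_bound}, younger={self.younger_bound}")

    @property
    def is_extant(self) -> bool:
        return self.older_bound == 0.0 and self.younger_bound == 0.0


@dataclass(frozen=True)
class NodeConstraint:
    """Minimum age (Ma) for the MRCA of a tip set."""

    tips: frozenset
    min_age: float

    def __post_init__(self):
        if self.min_age < 0:
            raise InputError(f"negative constraint age {self.min_age}")


# one constraint *set* = one clock-tree draw
NodeConstraintSet = Sequence[NodeConstraint]


@dataclass
class TimeScaleSpec:
    """Replication recipe for an ensemble of 'equal'-dated trees.

    ``fossil_age_mode`` is ``"older_bound"`` (first-appearance dates set
    to the oldest bound of the stratigraphic unit) or ``"uniform"``
    (drawn uniformly within the unit).  The three published tree-set
    recipes are: set #1 = resolve + older_bound; set #2 = unresolved +
    uniform; set #3 = resolve + uniform.
    """

    vartime: float = 1.0
    fossil_age_mode: str = "older_bound"
    resolve_polytomies: bool = True
    n_replicates: int = 1
    seed: int = 0
    method: str = "equal"

    def __post_init__(self):
        if self.method != "equal":
            raise InputError(f"unsupported time-scaling method {self.method!r}")
        if self.fossil_age_mode not in ("older_bound", "uniform"):
            raise InputError(f"unknown fossil_age_mode {self.fossil_age_mode!r}")
        if self.vartime <= 0:
            raise InputError("vartime must be positive")
        if self.n_replicates < 1:
            raise InputError("n_replicates must be >= 1")

    @classmethod
    def tree_set(cls, number: int, **kwargs) -> "TimeScaleSpec":
        recipes = {
            1: dict(resolve_polytomies=True, fossil_age_mode="older_bound"),
            2: dict(resolve_polytomies=False, fossil_age_mode="uniform"),
            3: dict(resolve_polytomies=True, fossil_age_mode="uniform"),
        }
        if number not in recipes:
            raise InputError(f"tree set must be 1, 2 or 3, got {number}")
        return cls(**{**recipes[number], **kwargs})


def resolve_polytomies_random(topology: Tree, rng: np.random.Generator) -> Tree:
    """Resolve every polytomy by recursive random pairing of children.

    Each step joins two uniformly chosen children of a polytomous node
    under a new (ageless) node, until the node is binary.  Every clade
    of the input is a clade of the output; the tip set is unchanged.
    """
    tree = topology.copy()
    for node in list(tree.preorder()):
        while len(node.children) > 2:
            i, j = sorted(rng.choice(len(node.children), size=2, replace=False))
            a, b = node.children[i], node.children[j]
            new = Node()
            new.add_child(a)
            new.add_child(b)
            node.children = [c for c in node.children if c is not a and c is not b]
            node.add_child(new)
    return tree


def sample_fossil_ages(
    ranges: Iterable[StratRange],
    mode: str,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Draw one age per tip from its stratigraphic range.

    ``older_bound`` mode returns the older bound exactly; ``uniform``
    draws from U(younger, older).  Extant tips always get 0.
    """
    if mode not in ("older_bound", "uniform"):
        raise InputError(f"unknown fossil age mode {mode!r}")
    ages = {}
    for r in ranges:
        if r.is_extant:
            ages[r.tip_id] = 0.0
        elif mode == "older_bound":
            ages[r.tip_id] = r.older_bound
        else:
            if rng is None:
                raise InputError("uniform mode needs an rng")
            ages[r.tip_id] = float(
                rng.uniform(r.younger_bound, r.older_bound))
    return ages


def _stage1_basic_ages(tree: Tree, tip_ages: dict,
                       constraints: NodeConstraintSet) -> None:
    """Set tip ages and minimum internal ages (stage 1 of 'equal')."""
    tips = set(tree.tip_labels)
    missing = tips - set(tip_ages)
    if missing:
        raise InputError(f"tips without ages: {sorted(missing)}")

    minima: dict[int, float] = {}
    for c in constraints:
        node = tree.mrca(c.tips)  # raises InputError on unknown tips
        key = id(node)
        minima[key] = max(minima.get(key, 0.0), c.min_age)

    for node in tree.postorder():
        if node.is_leaf:
            node.age = float(tip_ages[node.label])
        else:
            node.age = max(c.age for c in node.children)
            if id(node) in minima:
                node.age = max(node.age, minima[id(node)])


def _stage3_redistribute(tree: Tree) -> None:
    """Eliminate zero-duration branches ('equal' stage 3).

    Repeatedly take the *deepest* zero-duration branch (the bottom of a
    maximal zero chain; ties broken by preorder position), walk up to
    the nearest ancestral branch with positive duration, and respace the
    node ages along that whole path evenly.  Chains that branch share
    their upper portion with the first chain processed and are finished
    in later passes.  Root and tip ages (hence all root-to-tip spans)
    are untouched; node ages only increase, so constraint minima stay
    satisfied.
    """
    while True:
        target = None
        target_depth = -1
        depth: dict[int, int] = {id(tree.root): 0}
        for node in tree.preorder():
            if node.is_root:
                continue
            depth[id(node)] = depth[id(node.parent)] + 1
            if node.parent.age - node.age <= _ZERO and depth[id(node)] > target_depth:
                target = node
                target_depth = depth[id(node)]
        if target is None:
            return
        chain = [target]
        cur = target.parent
        while not cur.is_root and cur.parent.age - cur.age <= _ZERO:
            chain.append(cur)
            cur = cur.parent
        assert not cur.is_root, \
            "zero-duration branch directly below root (vartime not applied?)"
        top_age = cur.parent.age
        bottom_age = target.age
        n_edges = len(chain) + 1  # donor branch + the zero chain
        step = (top_age - bottom_age) / n_edges
        assert step > 0, "no positive ancestral duration to redistribute"
        movers = [cur] + chain[:0:-1]  # cur, then chain minus target, top-down
        for i, node in enumerate(movers, start=1):
            node.age = top_age - i * step


def time_scale_equal(
    topology: Tree,
    tip_ages: dict,
    constraints: NodeConstraintSet = (),
    vartime: float = 1.0,
) -> Tree:
    """Date a rooted topology with the three-stage 'equal' procedure.

    Stage 1 assigns each internal node the age of its oldest descendant
    tip, raised to any applicable constraint minimum (maxima propagate
    rootward automatically).  Stage 2 pushes the root back by
    ``vartime`` Myr.  Stage 3 shares that slack down every chain of
    zero-duration branches so all durations end positive.
    """
    if vartime <= 0:
        raise InputError("vartime must be positive")
    tree = topology.copy()
    _stage1_basic_ages(tree, tip_ages, constraints)
    tree.root.age += vartime
    _stage3_redistribute(tree)

    # contract checks: strictly positive durations, tip-age fidelity
    for node in tree.preorder():
        if node.is_root:
            continue
        d = node.parent.age - node.age
        assert d > 0, f"non-positive duration {d} above {node.label!r}"
        if node.is_leaf:
            assert abs(node.age - tip_ages[node.label]) <= 1e-9
    return tree


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Independent, reproducible substream for one replicate."""
    return np.random.default_rng(np.random.SeedSequence([seed, replicate]))


def build_tree_set(
    topology: Tree,
    ranges: Iterable[StratRange],
    constraint_collection: Sequence[NodeConstraintSet] = (),
    spec: TimeScaleSpec = TimeScaleSpec(),
    log: Optional[list] = None,
) -> list[Tree]:
    """Build ``spec.n_replicates`` dated trees.

    Per replicate: resolve polytomies (if requested), sample fossil
    ages, draw one constraint set uniformly from the collection, and
    apply 'equal' dating.  Each replicate uses an RNG substream derived
    from ``(spec.seed, replicate)`` so it is individually reproducible
    and unaffected by ``n_replicates``.
    """
    ranges = list(ranges)
    tips = set(topology.tip_labels)
    have = {r.tip_id for r in ranges}
    if not tips <= have:
        raise InputError(f"tips without stratigraphic ranges: {sorted(tips - have)}")

    trees = []
    for i in range(spec.n_replicates):
        rng = replicate_rng(spec.seed, i)
        topo = topology
        if spec.resolve_polytomies:
            topo = resolve_polytomies_random(topo, rng)
        ages = sample_fossil_ages(ranges, spec.fossil_age_mode, rng)
        if constraint_collection:
            idx = int(rng.integers(len(constraint_collection)))
            constraints = constraint_collection[idx]
        else:
            idx = None
            constraints = ()
        tree = time_scale_equal(topo, ages, constraints, spec.vartime)
        if log is not None:
            log.append({"replicate": i, "constraint_sample": idx,
                        "seed": [spec.seed, i],
                        "root_age": tree.root.age})
        trees.append(tree)
    return trees
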