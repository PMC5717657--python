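"""Synthetic data with known ground truth for every pipeline stage.

Generates birth–death chronograms that keep their extinct tips,
multivariate Brownian-motion trait histories (true internal values
retained), landmark configurations derived from those traits with random
nuisance similarity transforms, stratigraphic ranges guaranteed to
contain the true tip ages, and polytomy-injected topologies.  Everything
is reproducible bit-exactly from (seed, parameters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .morphometry import LandmarkConfiguration
from .trees import InputError, Node, Tree
from .treetime import StratRange

__all__ = [
    "BMParams",
    "BirthDeathParams",
    "simulate_birth_death_tree",
    "simulate_bm_traits",
    "simulate_landmark_shapes",
    "assign_strat_ranges",
    "inject_polytomies",
    "make_constraint_sets",
    "regular_units",
    "default_mean_shape",
    "SyntheticDataset",
    "make_dataset",
]

logger = logging.getLogger(__name__)


@dataclass
class BMParams:
    """Brownian-motion trait model: variance ``rate`` per Myr per
    dimension, common to all ``p`` dimensions."""

    rate: float = 1.0
    root_value: Optional[np.ndarray] = None
    p: int = 1

    def __post_init__(self):
        if self.rate < 0:
            raise InputError("BM rate must be >= 0")
        if self.p < 1:
            raise InputError("p must be >= 1")
        if self.root_value is None:
            self.root_value = np.zeros(self.p)
        else:
            self.root_value = np.asarray(self.root_value, dtype=float)
            if self.root_value.shape != (self.p,):
                raise InputError("root_value must be a p-vector")


@dataclass
class BirthDeathParams:
    """Constant-rate birth–death process, crown-conditioned (two initial
    lineages), stopped either at a fixed ``depth`` (Myr) or when
    ``n_extant`` lineages are simultaneously alive."""

    birth: float = 0.1
    death: float = 0.05
    n_extant: Optional[int] = None
    depth: Optional[float] = None
    max_retries: int = 1000

    def __post_init__(self):
        if self.birth <= 0 or self.death < 0:
            raise InputError("need birth > 0 and death >= 0")
        if (self.n_extant is None) == (self.depth is None):
            raise InputError("set exactly one of n_extant / depth")
        if self.n_extant is not None and self.n_extant < 2:
            raise InputError("n_extant must be >= 2")


def simulate_birth_death_tree(
    params: BirthDeathParams, rng: np.random.Generator
) -> Tree:
    """Simulate a crown-conditioned birth–death chronogram.

    Extinct tips are retained with their extinction ages; extant tips
    sit at age 0.  Replicates in which the clade dies out entirely (or,
    under the ``n_extant`` stop rule, never reaches the target) are
    rejected and redrawn, with the retry count logged.
    """
    for attempt in range(params.max_retries):
        result = _simulate_bd_tree_ages(params, rng)
        if result is not None:
            if attempt:
                logger.info("birth-death simulation succeeded after %d "
                            "rejected attempts", attempt)
            return result
    raise InputError(
        f"birth-death simulation failed {params.max_retries} times "
        "(total extinction); lower the death rate or the target size")


def _simulate_bd_tree_ages(params, rng) -> Optional[Tree]:
    """Single attempt, tracking split times on nodes directly."""
    root = Node()
    birth, death = params.birth, params.death
    total = birth + death
    split_time = {id(root): 0.0}
    active: list[Node] = [root.add_child(Node()), root.add_child(Node())]
    tip_time: dict[int, float] = {}
    t = 0.0
    t_end = None
    for _ in range(400_000):
        n = len(active)
        if n == 0:
            return None
        if params.n_extant is not None and n == params.n_extant:
            t_end = t + rng.exponential(1.0 / (n * total))
            break
        wait = rng.exponential(1.0 / (n * total))
        if params.depth is not None and t + wait >= params.depth:
            t_end = params.depth
            break
        t += wait
        i = int(rng.integers(n))
        node = active.pop(i)
        if rng.random() < birth / total:
            split_time[id(node)] = t
            active.append(node.add_child(Node()))
            active.append(node.add_child(Node()))
        else:
            tip_time[id(node)] = t
    else:
        raise InputError("birth-death simulation exceeded event cap; "
                         "reduce rates or target size")

    if params.depth is not None and not active:
        return None
    for node in active:
        tip_time[id(node)] = t_end

    tree = Tree(root)
    for node in tree.preorder():
        if node.is_leaf:
            node.age = t_end - tip_time[id(node)]
        else:
            node.age = t_end - split_time[id(node)]
    # extant check under the depth rule (any tip at age 0)
    if params.depth is not None and not any(
            node.age == 0.0 for node in tree.tips()):
        return None
    for i, tip in enumerate(tree.tips()):
        tip.label = f"t{i + 1}"
    return tree


def simulate_bm_traits(
    tree: Tree, params: BMParams, rng: np.random.Generator
) -> tuple[dict, Tree]:
    """Forward-simulate BM on a dated tree.

    Returns ``(tip_traits, true_tree)`` where ``true_tree`` is a copy
    carrying the simulated value at *every* node, so ancestral-state
    recovery can be scored against the truth.
    """
    out = tree.copy()
    sd = np.sqrt(params.rate)
    for node in out.preorder():
        if node.is_root:
            node.traits = params.root_value.copy()
        else:
            v = node.parent.age - node.age
            if v < 0:
                raise InputError("negative branch duration in input tree")
            step = rng.normal(0.0, sd * np.sqrt(v), size=params.p)
            node.traits = node.parent.traits + step
    tip_traits = {t.label: t.traits.copy() for t in out.tips()}
    return tip_traits, out


def default_mean_shape(k: int = 12) -> np.ndarray:
    """A non-degenerate reference configuration: k points on an ellipse."""
    theta = np.linspace(0, 2 * np.pi, k, endpoint=False)
    return np.column_stack([2.0 * np.cos(theta), np.sin(theta)])


def simulate_landmark_shapes(
    mean_shape: np.ndarray,
    tree: Tree,
    params: BMParams,
    rng: np.random.Generator,
) -> tuple[list[LandmarkConfiguration], dict]:
    """Landmark configurations whose shape variation is BM on the tree.

    Each tip's flattened deviation from ``mean_shape`` evolves by BM
    (``params.p`` must equal 2k); the emitted configuration is then hit
    with a random similarity nuisance transform — rotation ~ U(0, 2π),
    scale ~ exp(N(0, 0.1)), translation ~ N(0, 10·shape scale) — which
    Procrustes alignment must remove.  Returns the configurations and
    the underlying true deviations per tip.
    """
    mean_shape = np.asarray(mean_shape, dtype=float)
    k = mean_shape.shape[0]
    if mean_shape.shape != (k, 2) or k < 3:
        raise InputError("mean_shape must be (k >= 3, 2)")
    centered = mean_shape - mean_shape.mean(axis=0)
    scale0 = np.sqrt((centered ** 2).sum())
    if scale0 <= 0:
        raise InputError("degenerate mean shape")
    if params.p != 2 * k:
        raise InputError(f"params.p must be 2k = {2 * k}")

    tip_traits, _ = simulate_bm_traits(tree, params, rng)
    configs = []
    for tip in tree.tips():
        dev = tip_traits[tip.label]
        coords = mean_shape + dev.reshape(k, 2)
        angle = rng.uniform(0.0, 2 * np.pi)
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        scale = np.exp(rng.normal(0.0, 0.1))
        shift = rng.normal(0.0, 10.0 * scale0, size=2)
        configs.append(LandmarkConfiguration(
            tip.label, coords @ rot.T * scale + shift))
    return configs, tip_traits


def regular_units(span: float, width: float) -> list[tuple[float, float]]:
    """Contiguous stratigraphic units of equal width tiling (0, span]."""
    edges = np.arange(0.0, span + width, width)
    return [(float(b), float(a)) for a, b in zip(edges, edges[1:])][::-1]


def assign_strat_ranges(
    tree: Tree,
    unit_table: Sequence[tuple],
    rng: Optional[np.random.Generator] = None,
) -> list[StratRange]:
    """Replace each tip's true age by its containing stratigraphic unit.

    Units are (older, younger) pairs; a fossil of true age a falls in
    the unit with ``younger < a <= older``, so any age redrawn from the
    assigned range can bracket the truth.  Extant tips (age 0) get
    (0, 0).
    """
    ranges = []
    for tip in tree.tips():
        if tip.age is None:
            raise InputError(f"tip {tip.label!r} has no age")
        if tip.age == 0.0:
            ranges.append(StratRange(tip.label, 0.0, 0.0))
            continue
        for older, younger in unit_table:
            if younger < tip.age <= older:
                ranges.append(StratRange(tip.label, older, younger))
                break
        else:
            raise InputError(
                f"tip {tip.label!r} age {tip.age:g} outside all units")
    return ranges


def inject_polytomies(
    tree: Tree, fraction: float, rng: np.random.Generator
) -> Tree:
    """Collapse a fraction of internal edges into polytomies.

    Returns a bare topology (ages and branch lengths discarded), as a
    supertree with unresolved nodes would arrive.
    """
    if not 0 <= fraction < 1:
        raise InputError("fraction must be in [0, 1)")
    topo = tree.copy()
    for node in topo.preorder():
        node.age = None
        node.length = None
    candidates = [n for n in topo.preorder()
                  if not n.is_leaf and not n.is_root]
    n_collapse = int(round(fraction * len(candidates)))
    if n_collapse == 0:
        return topo
    chosen = rng.choice(len(candidates), size=n_collapse, replace=False)
    for i in sorted(chosen, reverse=True):
        node = candidates[i]
        parent = node.parent
        parent.children.remove(node)
        for c in list(node.children):
            parent.add_child(c)
    return topo


def make_constraint_sets(
    tree: Tree,
    n_sets: int,
    rng: np.random.Generator,
    include_prob: float = 0.8,
    rel_scatter: float = 0.1,
) -> list:
    """Emulate node-age minimum constraints from a clock-tree sample.

    Molecular-clock studies date the divergences of *extant* lineages,
    so each set constrains the MRCAs of extant tip groups: every
    internal node of the true chronogram that is the exact MRCA of its
    extant descendants is included with probability ``include_prob``.
    The enforced minimum is the sampled clock estimate of the node age,
    drawn as ``true age x U(1 - rel_scatter, 1 + rel_scatter)`` —
    posterior samples scatter around the truth, over- as well as
    under-shooting it.  One set per draw emulates one posterior sample.
    """
    from .treetime import NodeConstraint

    extant = {t.label for t in tree.tips() if t.age == 0.0}
    candidates = []
    for node in tree.internal_nodes():
        below = {t.label for t in Tree(node).tips()} & extant
        if len(below) >= 2 and tree.mrca(below) is node:
            candidates.append((frozenset(below), node.age))
    sets = []
    for _ in range(n_sets):
        entries = []
        for tips, true_age in candidates:
            if rng.random() < include_prob:
                entries.append(NodeConstraint(
                    tips, float(true_age * rng.uniform(1.0 - rel_scatter,
                                                       1.0 + rel_scatter))))
        sets.append(entries)
    return sets


@dataclass
class SyntheticDataset:
    """One fully specified synthetic study with ground truth attached."""

    true_tree: Tree            # dated, extinct tips retained
    true_trait_tree: Tree      # same tree with true values at all nodes
    topology: Tree             # polytomy-injected, undated
    ranges: list               # StratRange per tip
    tip_traits: dict           # tip -> p-vector (true tip values)
    constraint_sets: list = field(default_factory=list)  # clock-tree minima
    configs: list = field(default_factory=list)  # landmark configurations


def make_dataset(
    seed: int = 0,
    n_extant: int = 40,
    birth: float = 0.1,
    death: float = 0.05,
    bm_rate: float = 1.0,
    p: int = 7,
    k_landmarks: int = 12,
    polytomy_fraction: float = 0.3,
    unit_width: float = 10.0,
    n_constraint_sets: int = 50,
    with_landmarks: bool = False,
) -> SyntheticDataset:
    """Default study conditions: a birth–death clade stopped at 40
    extant tips (birth 0.1/Myr, death 0.05/Myr, depth on the order of
    100 Myr), 7 trait dimensions, 12 landmarks, 30% of internal edges
    collapsed, 10-Myr stratigraphic units, and 50 clock-tree constraint
    sets on the divergences of extant lineages."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9001]))
    bd = BirthDeathParams(birth=birth, death=death, n_extant=n_extant)
    tree = simulate_birth_death_tree(bd, rng)
    bm = BMParams(rate=bm_rate, p=p)
    tip_traits, true_trait_tree = simulate_bm_traits(tree, bm, rng)
    units = regular_units(tree.root.age + unit_width, unit_width)
    ranges = assign_strat_ranges(tree, units, rng)
    topology = inject_polytomies(tree, polytomy_fraction, rng)
    constraint_sets = make_constraint_sets(tree, n_constraint_sets, rng)
    configs = []
    if with_landmarks:
        shape_bm = BMParams(rate=1e-4, p=2 * k_landmarks)
        configs, _ = simulate_landmark_shapes(
            default_mean_shape(k_landmarks), tree, shape_bm, rng)
    return SyntheticDataset(
        true_tree=tree, true_trait_tree=true_trait_tree, topology=topology,
        ranges=ranges, tip_traits=tip_traits,
        constraint_sets=constraint_sets, configs=configs)
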