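"""Ancestral trait values under Brownian motion (squared-change parsimony).

For a continuous trait evolving by Brownian motion on a dated tree, the
maximum-likelihood point estimates of internal-node values minimise

    sum over branches of (x_child - x_parent)^2 / v,

where v is the branch duration — the duration-weighted squared-change
parsimony criterion.  The diffusion rate cancels in the point estimates,
so it is not estimated, and each trait dimension decouples, so a
p-dimensional trait is p independent one-dimensional problems solved
jointly on arrays.

The solver is the classic two-pass pruning algorithm: a tip-to-root pass
contracts each subtree into a conditional value with an effective extra
duration, and a root-to-tip pass combines each node's conditional value
with its parent's finalised estimate.  Cost is O(n * p).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .trees import InputError, Tree

__all__ = ["ancestral_states", "node_estimates_frame"]

_EPS = 1e-8  # duration floor, Myr


def ancestral_states(tree: Tree, tip_traits: dict) -> Tree:
    """Estimate trait vectors at every internal node.

    Parameters
    ----------
    tree : Tree
        Dated tree (every node has an age, durations positive; durations
        below ``1e-8`` Myr are floored with a warning).
    tip_traits : dict
        ``tip label -> p-vector`` of observed trait values.

    Returns
    -------
    Tree
        A copy with ``node.traits`` set on every node: tip values are
        the observations, internal values the BM/ML point estimates.
    """
    out = tree.copy()
    tips = out.tips()
    missing = [t.label for t in tips if t.label not in tip_traits]
    if missing:
        raise InputError(f"tips without trait values: {missing}")

    first = np.atleast_1d(np.asarray(tip_traits[tips[0].label], dtype=float))
    p = first.shape[0]
    for t in tips:
        v = np.atleast_1d(np.asarray(tip_traits[t.label], dtype=float))
        if v.shape != (p,):
            raise InputError(
                f"trait-dimension mismatch at tip {t.label!r}: "
                f"{v.shape} vs ({p},)")
        if not np.all(np.isfinite(v)):
            raise InputError(f"non-finite trait value at tip {t.label!r}")
        t.traits = v.copy()

    def branch(node) -> float:
        v = node.parent.age - node.age
        if v < _EPS:
            warnings.warn(
                f"branch above {node.label!r} has duration {v:g} Myr; "
                f"floored at {_EPS:g}", stacklevel=3)
            v = _EPS
        return v

    # tip-to-root: conditional value and effective extra duration per node
    cond: dict[int, np.ndarray] = {}
    extra: dict[int, float] = {}
    for node in out.postorder():
        if node.is_leaf:
            cond[id(node)] = node.traits
            extra[id(node)] = 0.0
        else:
            weights = []
            for c in node.children:
                length = extra[id(c)] + branch(c)
                weights.append(1.0 / length)
            weights = np.asarray(weights)
            values = np.stack([cond[id(c)] for c in node.children])
            cond[id(node)] = weights @ values / weights.sum()
            extra[id(node)] = 1.0 / weights.sum()

    # root-to-tip finalisation
    for node in out.preorder():
        if node.is_leaf:
            continue
        if node.is_root:
            node.traits = cond[id(node)].copy()
        else:
            v = branch(node)
            t = extra[id(node)]
            a = node.parent.traits
            u = cond[id(node)]
            w_down, w_up = 1.0 / t if t > 0 else np.inf, 1.0 / v
            if np.isinf(w_down):  # exact conditional (degenerate subtree)
                node.traits = u.copy()
            else:
                node.traits = (w_down * u + w_up * a) / (w_down + w_up)
    return out


def node_estimates_frame(tree: Tree) -> pd.DataFrame:
    """Tabulate node ages and trait vectors (tips and internal nodes)."""
    tree.assign_internal_labels()
    rows = []
    for node in tree.preorder():
        if node.traits is None:
            raise InputError(f"node {node.label!r} has no traits")
        rows.append({"node": node.label,
                     "is_tip": node.is_leaf,
                     "age": node.age,
                     **{f"PC{i + 1}": v for i, v in enumerate(node.traits)}})
    return pd.DataFrame(rows)
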