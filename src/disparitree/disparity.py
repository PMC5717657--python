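"""Disparity through time from branch-interpolated trait values.

Lineages crossing a time bin are sampled at the bin's temporal midpoint
by linear interpolation of trait values along each branch between its
parent and child nodes (the "gradual" model of trait change).  Disparity
per bin is the sum over retained trait dimensions of the sample variance
(n-1 denominator) of those interpolated values — only interpolated
branch samples enter; no separate terminal or node values are appended.
Repeating over an ensemble of dated trees yields per-bin median,
quantile and full-range summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .trees import InputError, Tree

__all__ = [
    "TimeBin",
    "LineageSlice",
    "DisparityCurve",
    "DisparityEnsemble",
    "make_bins",
    "interpolate_at_time",
    "sum_of_variances",
    "disparity_curve",
    "ensemble_summary",
    "clade_subset",
    "drop_fossils",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimeBin:
    """A named stratigraphic interval [older, younger] in Ma.

    ``older > younger`` for ordinary bins; a degenerate point bin with
    ``older == younger`` (used for a Recent bin sampled exactly at
    0 Ma) is allowed.
    """

    name: str
    older: float
    younger: float

    def __post_init__(self):
        if self.younger < 0 or self.older < self.younger:
            raise InputError(
                f"invalid bin {self.name!r}: older={self.older}, "
                f"younger={self.younger}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.older + self.younger)


def validate_bin_series(bins: Sequence[TimeBin]) -> None:
    """Bins must be ordered old -> young and non-overlapping."""
    for a, b in zip(bins, bins[1:]):
        if b.older > a.younger + 1e-12:
            raise InputError(
                f"bins {a.name!r} and {b.name!r} overlap or are out of order")


def make_bins(boundaries: Sequence[float],
              names: Optional[Sequence[str]] = None) -> list[TimeBin]:
    """Build contiguous bins from boundary ages ordered old -> young."""
    bounds = list(boundaries)
    if any(a <= b for a, b in zip(bounds, bounds[1:])):
        raise InputError("boundaries must strictly decrease (old -> young)")
    if names is None:
        names = [f"bin{i}" for i in range(len(bounds) - 1)]
    bins = [TimeBin(n, o, y) for n, o, y in zip(names, bounds, bounds[1:])]
    validate_bin_series(bins)
    return bins


@dataclass
class LineageSlice:
    """Interpolated trait values of all branches crossing one time."""

    t: float
    branch_ids: list
    values: np.ndarray  # (n_lineages, p)

    @property
    def n_lineages(self) -> int:
        return len(self.branch_ids)


def interpolate_at_time(tm_tree: Tree, t: float) -> LineageSlice:
    """Sample every lineage alive at time ``t`` (Ma).

    A branch from parent (age a_p, value x_p) to child (age a_c, value
    x_c) contributes ``x_p + (x_c - x_p) * (a_p - t) / (a_p - a_c)``
    when ``a_c <= t < a_p``; the half-open rule plus the root's own
    value at ``t == root age`` counts a node sitting exactly at ``t``
    once, via its parent branch.  Times older than the root give an
    empty slice.
    """
    if t < 0:
        raise InputError(f"negative time {t}")
    tm_tree.assign_internal_labels()
    ids: list = []
    vals: list = []
    root = tm_tree.root
    if t == root.age:
        if root.traits is None:
            raise InputError("tree has no trait values; run ancestral_states")
        ids.append(root.label)
        vals.append(np.atleast_1d(root.traits))
    for node in tm_tree.preorder():
        if node.is_root:
            continue
        a_c, a_p = node.age, node.parent.age
        if a_c <= t < a_p:
            if node.traits is None or node.parent.traits is None:
                raise InputError("tree has no trait values; run ancestral_states")
            x_c = np.atleast_1d(node.traits)
            x_p = np.atleast_1d(node.parent.traits)
            frac = (a_p - t) / (a_p - a_c)
            ids.append(node.label)
            vals.append(x_p + (x_c - x_p) * frac)
    if vals:
        values = np.stack(vals)
    else:
        values = np.empty((0, 0))
    return LineageSlice(t=t, branch_ids=ids, values=values)


def sum_of_variances(slice_: LineageSlice) -> Optional[float]:
    """Sum over trait dimensions of the sample variance of the slice.

    Undefined (``None``) for fewer than two lineages — a bin sampled by
    a single lineage has no measurable disparity, which is reported as
    missing rather than zero.
    """
    if slice_.n_lineages < 2:
        logger.debug("slice at %.4g Ma has %d lineage(s); SoV undefined",
                     slice_.t, slice_.n_lineages)
        return None
    return float(np.var(slice_.values, axis=0, ddof=1).sum())


@dataclass
class DisparityCurve:
    """Per-bin sum of variances and lineage counts for one dated tree."""

    bins: list
    sov: np.ndarray          # (n_bins,), NaN where undefined
    n_lineages: np.ndarray   # (n_bins,), int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin": [b.name for b in self.bins],
            "midpoint": [b.midpoint for b in self.bins],
            "n_lineages": self.n_lineages,
            "sum_of_variances": self.sov,
        })


def disparity_curve(tm_tree: Tree, bins: Sequence[TimeBin]) -> DisparityCurve:
    """Sum-of-variances disparity at every bin midpoint."""
    validate_bin_series(bins)
    sov = np.full(len(bins), np.nan)
    counts = np.zeros(len(bins), dtype=int)
    for i, b in enumerate(bins):
        sl = interpolate_at_time(tm_tree, b.midpoint)
        counts[i] = sl.n_lineages
        s = sum_of_variances(sl)
        if s is not None:
            sov[i] = s
    return DisparityCurve(bins=list(bins), sov=sov, n_lineages=counts)


@dataclass
class DisparityEnsemble:
    """Cross-replicate summary of disparity curves on a shared bin series."""

    bins: list
    median: np.ndarray
    q025: np.ndarray
    q975: np.ndarray
    low: np.ndarray
    high: np.ndarray
    n_lineages_median: np.ndarray
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin": [b.name for b in self.bins],
            "midpoint": [b.midpoint for b in self.bins],
            "n_lineages_median": self.n_lineages_median,
            "median": self.median,
            "q2.5": self.q025,
            "q97.5": self.q975,
            "min": self.low,
            "max": self.high,
        })


def ensemble_summary(curves: Sequence[DisparityCurve]) -> DisparityEnsemble:
    """Per-bin median, 2.5/97.5% quantiles and full range over replicates.

    Replicates with an undefined SoV in a bin are dropped from that
    bin's summary; a bin undefined in every replicate is reported
    missing (NaN).
    """
    if not curves:
        raise InputError("need at least one curve")
    ref = curves[0].bins
    for c in curves[1:]:
        if [(b.name, b.older, b.younger) for b in c.bins] != \
           [(b.name, b.older, b.younger) for b in ref]:
            raise InputError("curves computed on different bin series")
    nb = len(ref)
    med = np.full(nb, np.nan)
    q025 = np.full(nb, np.nan)
    q975 = np.full(nb, np.nan)
    low = np.full(nb, np.nan)
    high = np.full(nb, np.nan)
    counts = np.stack([c.n_lineages for c in curves])
    sov = np.stack([c.sov for c in curves])
    for i in range(nb):
        col = sov[:, i]
        col = col[~np.isnan(col)]
        if col.size:
            med[i] = np.median(col)
            q025[i] = np.quantile(col, 0.025)
            q975[i] = np.quantile(col, 0.975)
            low[i] = col.min()
            high[i] = col.max()
    return DisparityEnsemble(
        bins=list(ref), median=med, q025=q025, q975=q975, low=low, high=high,
        n_lineages_median=np.median(counts, axis=0),
        n_replicates=len(curves),
    )


def clade_subset(tm_tree: Tree, tip_set: Iterable[str]) -> Tree:
    """Subtree rooted at the MRCA of ``tip_set``.

    Node ages and trait values are carried over unchanged — ancestral
    values are *not* re-estimated, so a whole-tree slice restricted to
    the clade equals the clade-subset slice exactly.
    """
    tip_set = list(tip_set)
    if not tip_set:
        raise InputError("empty tip set")
    mrca = tm_tree.mrca(tip_set)

    def rec(node):
        from .trees import Node
        new = Node(node.label, node.age, node.length)
        if node.traits is not None:
            new.traits = node.traits.copy()
        for c in node.children:
            new.add_child(rec(c))
        return new

    return Tree(rec(mrca))


def drop_fossils(topology: Tree, ranges: Sequence) -> tuple[Tree, list]:
    """Restrict a topology and its age ranges to extant tips.

    Fossil tips (any tip whose range is not exactly 0/0) are removed and
    resulting degree-2 nodes suppressed with their edge lengths summed,
    so paths between the remaining tips are unchanged.
    """
    by_tip = {r.tip_id: r for r in ranges}
    missing = set(topology.tip_labels) - set(by_tip)
    if missing:
        raise InputError(f"tips without ranges: {sorted(missing)}")
    extant = [t for t in topology.tip_labels if by_tip[t].is_extant]
    if len(extant) < 2:
        raise InputError("fewer than 2 extant tips; cannot drop fossils")
    pruned = topology.prune_to(extant)
    return pruned, [by_tip[t] for t in extant]
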