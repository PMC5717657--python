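"""Ribbon plot of an ensemble disparity curve."""

from __future__ import annotations

from .disparity import DisparityEnsemble

__all__ = ["plot_ensemble"]


def plot_ensemble(ensemble: DisparityEnsemble, ax=None, label=None,
                  color="tab:blue"):
    """Median disparity with 2.5–97.5% quantile and full-range bands.

    Time runs from the oldest bin midpoint (left) to the Recent; the
    x-axis is age in Ma, inverted.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = [b.midpoint for b in ensemble.bins]
    ax.fill_between(x, ensemble.low, ensemble.high, alpha=0.15,
                    color="gold", label="full range")
    ax.fill_between(x, ensemble.q025, ensemble.q975, alpha=0.3,
                    color="cyan", label="2.5–97.5%")
    ax.plot(x, ensemble.median, color=color, label=label or "median")
    if not ax.xaxis_inverted():
        ax.invert_xaxis()
    ax.set_xlabel("age (Ma)")
    ax.set_ylabel("sum of variances")
    return ax
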