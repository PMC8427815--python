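"""Schematic scalp topographies of channel-wise statistics.

Renders a head circle with one marker per electrode, coloured by a signed
per-channel value (e.g. the observed group difference in mean HFD), with
optional significance rings: grey for uncorrected, black for
Bonferroni-corrected channels.  Purely diagnostic output; montage
coordinates are schematic, not anatomical.
"""

from __future__ import annotations

import numpy as np

from .montage import ChannelMontage
from .stats import ComparisonResult

__all__ = ["plot_topomap", "plot_comparison"]


def plot_topomap(montage: ChannelMontage, values, ax=None, cmap="RdBu_r",
                 vlim=None, label_channels=False):
    """Scatter ``values`` (one per montage channel) on the head circle."""
    import matplotlib.pyplot as plt

    values = np.asarray(values, dtype=float)
    if values.shape != (len(montage),):
        raise ValueError("values must have one entry per montage channel")
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    lim = float(np.nanmax(np.abs(values))) if vlim is None else vlim
    lim = lim or 1.0
    head = plt.Circle((0, 0), 1.0, fill=False, lw=1.5, color="k")
    ax.add_patch(head)
    ax.plot([-0.08, 0, 0.08], [0.995, 1.08, 0.995], color="k", lw=1.5)  # nose
    sc = ax.scatter(montage.positions[:, 0], montage.positions[:, 1],
                    c=values, cmap=cmap, vmin=-lim, vmax=lim, s=80,
                    edgecolors="none", zorder=3)
    if label_channels:
        for name, (x, y) in zip(montage.names, montage.positions):
            ax.annotate(name, (x, y), fontsize=5, ha="center", va="bottom",
                        xytext=(0, 4), textcoords="offset points")
    ax.set_xlim(-1.2, 1.2)
    ax.set_ylim(-1.2, 1.2)
    ax.set_aspect("equal")
    ax.axis("off")
    plt.colorbar(sc, ax=ax, shrink=0.75)
    return ax


def plot_comparison(result: ComparisonResult, montage: ChannelMontage, ax=None):
    """Topography of one group comparison with significance rings."""
    mont = montage.subset(list(result.channels))
    ax = plot_topomap(mont, result.differences, ax=ax)
    unc = set(result.significant_channels(corrected=False))
    cor = set(result.significant_channels(corrected=True))
    for name, (x, y) in zip(mont.names, mont.positions):
        if name in cor:
            ax.scatter([x], [y], s=150, facecolors="none", edgecolors="k",
                       linewidths=1.8, zorder=4)
        elif name in unc:
            ax.scatter([x], [y], s=150, facecolors="none", edgecolors="grey",
                       linewidths=1.4, zorder=4)
    ax.set_title(
        f"{result.pair[0]} - {result.pair[1]}, {result.task}, "
        f"{result.window_offset:g} s"
    )
    return ax
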