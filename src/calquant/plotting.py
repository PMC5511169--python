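"""Optional diagnostic plots: complex-plane signatures and population bars."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from matplotlib.figure import Figure

from .classify import FourierSignature
from .population import ReplicateAggregate


def complex_plane_figure(
    signature: FourierSignature, title: Optional[str] = None
) -> Figure:
    """Scatter the non-DC DFT components with the triggering radius circle."""
    fig = Figure(figsize=(4, 4))
    ax = fig.add_subplot(111)
    comps = signature.components
    ax.scatter(comps.real, comps.imag, s=6, alpha=0.6, label="components")
    theta = np.linspace(0, 2 * np.pi, 200)
    r = signature.radius_used
    ax.plot(r * np.cos(theta), r * np.sin(theta), "r-", lw=1, label="triggering radius")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel("Re")
    ax.set_ylabel("Im")
    ax.set_aspect("equal")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", fontsize="small")
    return fig


def population_bars_figure(
    aggregates: Sequence[ReplicateAggregate], metric: str = "single_peak_fraction"
) -> Figure:
    """Mean +/- sd bars of a replicate-level fraction per condition."""
    fig = Figure(figsize=(1.2 * len(aggregates) + 2, 3.5))
    ax = fig.add_subplot(111)
    labels = [a.condition_label or str(i) for i, a in enumerate(aggregates)]
    means = [getattr(a, f"{metric}_mean") for a in aggregates]
    sds = [getattr(a, f"{metric}_sd") for a in aggregates]
    ax.bar(labels, means, yerr=sds, capsize=4, color="0.7", edgecolor="k")
    ax.set_ylabel(metric.replace("_", " "))
    ax.set_ylim(0, None)
    return fig
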