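"""Basic dendrogram plotting (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
from scipy.cluster import hierarchy

from .clustering import Dendrogram


def plot_dendrogram(dend: Dendrogram, ax=None, title: str | None = None):
    """Draw a merge tree with disease-code leaf labels; returns the Axes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 5))
    hierarchy.dendrogram(
        dend.to_linkage(),
        labels=list(dend.leaves),
        leaf_rotation=90,
        ax=ax,
        color_threshold=0.0,
    )
    ax.set_ylabel("merge height (1 - Yule's Q scale)")
    if title:
        ax.set_title(title)
    ax.figure.tight_layout()
    return ax


def save_dendrogram(dend: Dendrogram, path, title: str | None = None) -> None:
    ax = plot_dendrogram(dend, title=title)
    ax.figure.savefig(path, dpi=120)
    plt.close(ax.figure)
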