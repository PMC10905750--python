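"""Figure helpers for shape-space results.

Thin matplotlib wrappers used by the example scripts: UMAP scatter by
cluster, the abstracted cluster graph (edges under the display
threshold of 0.1 are not drawn; the stored matrix is never
thresholded), and polar maps of cell locations.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .clustering import CONNECTIVITY_DISPLAY_THRESHOLD, _paga_layout

__all__ = ["plot_umap", "plot_cluster_graph", "plot_polar_locations"]


def plot_umap(xy: np.ndarray, labels: np.ndarray, ax=None, title: str = ""):
    """Scatter the 2D embedding colored by cluster label."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    labels = np.asarray(labels)
    for c in np.unique(labels):
        sel = labels == c
        ax.scatter(xy[sel, 0], xy[sel, 1], s=12, label=f"cluster {c}")
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend(fontsize=7)
    if title:
        ax.set_title(title)
    return ax


def plot_cluster_graph(connectivity: np.ndarray, sizes: np.ndarray,
                       ax=None, seed: int = 0):
    """Draw the cluster graph; line width scales with connectivity."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    k = connectivity.shape[0]
    pos = _paga_layout(np.arange(k), connectivity, seed)
    for i in range(k):
        for j in range(i + 1, k):
            w = connectivity[i, j]
            if w < CONNECTIVITY_DISPLAY_THRESHOLD:
                continue
            ax.plot(*zip(pos[i], pos[j]), color="gray", lw=1 + 2 * w, zorder=1)
            mid = (pos[i] + pos[j]) / 2
            ax.annotate(f"{w:.2f}", mid, fontsize=7, color="dimgray")
    s = 200 * np.asarray(sizes) / max(np.max(sizes), 1)
    ax.scatter(pos[:, 0], pos[:, 1], s=s, zorder=2)
    for i in range(k):
        ax.annotate(str(i), pos[i], ha="center", va="center", fontsize=9)
    ax.set_axis_off()
    return ax


def plot_polar_locations(d: np.ndarray, a_deg: np.ndarray,
                         groups: np.ndarray | None = None, ax=None):
    """Cells on the unit disk at (normalized distance, adjusted angle)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4),
                             subplot_kw={"projection": "polar"})
    theta = np.radians(np.asarray(a_deg, dtype=float))
    if groups is None:
        ax.scatter(theta, d, s=12)
    else:
        groups = np.asarray(groups)
        for g in np.unique(groups):
            sel = groups == g
            ax.scatter(theta[sel], d[sel], s=12, label=str(g))
        ax.legend(fontsize=7, loc="upper right")
    ax.set_rmax(1.05)
    return ax
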