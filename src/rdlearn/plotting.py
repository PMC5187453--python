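"""Thin optional plotting helpers (matplotlib imported lazily; numeric
outputs are always exported by the analysis functions themselves)."""

from __future__ import annotations

import numpy as np


def plot_mds(coords, labels, ax=None):
    """Scatter a 2-D MDS embedding of model/layer RDMs with text labels."""
    import matplotlib.pyplot as plt

    coords = np.asarray(coords)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(coords[:, 0], coords[:, 1])
    for (x, y), label in zip(coords, labels):
        ax.annotate(str(label), (x, y), textcoords="offset points",
                    xytext=(4, 4), fontsize=8)
    ax.set_xlabel("MDS axis 1")
    ax.set_ylabel("MDS axis 2")
    ax.set_aspect("equal")
    return ax


def plot_rdm(rdm, ax=None, cmap="viridis"):
    """Heat-map of a single RDM, ordered as its input identifiers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(rdm.values, cmap=cmap)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(f"RDM ({rdm.dissimilarity})", fontsize=9)
    return ax
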