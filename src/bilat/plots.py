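"""Minimal optional plotting: confusion heatmaps and index histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .decoding import DecodeResult

__all__ = ["plot_confusion", "plot_index_histogram"]


def plot_confusion(result: DecodeResult, ax=None, title: str | None = None):
    """Row-normalized confusion heatmap (true class x predicted class, %)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(result.confusion_pct, vmin=0, vmax=100, cmap="viridis")
    ax.set_xticks(range(len(result.classes)), result.classes, rotation=90, fontsize=7)
    ax.set_yticks(range(len(result.classes)), result.classes, fontsize=7)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    if title:
        ax.set_title(title)
    plt.colorbar(im, ax=ax, label="% of trials")
    return ax


def plot_index_histogram(uni_index, bi_index=None, ax=None):
    """Histogram of contralateral preference indices, optionally for both tasks."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    bins = np.linspace(-1, 1, 21)
    ax.hist(np.asarray(uni_index, float), bins=bins, alpha=0.6, label="unimanual")
    if bi_index is not None:
        ax.hist(np.asarray(bi_index, float), bins=bins, alpha=0.6, label="bimanual")
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("contralateral preference index")
    ax.set_ylabel("units")
    ax.legend(frameon=False)
    return ax
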