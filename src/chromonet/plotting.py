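"""Minimal matplotlib helpers for the standard diagnostic figures."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evaluate import StratifiedDistribution  # noqa: E402

__all__ = ["plot_stratified", "plot_distance_heatmap", "plot_scatter"]


def plot_stratified(dist: StratifiedDistribution, path, ylabel: str = "value") -> None:
    """Box plot of the groups of a stratified distribution."""
    labels = [k for k, v in dist.groups.items() if len(v)]
    data = [np.asarray(dist.groups[k], dtype=float) for k in labels]
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(labels), 4))
    ax.boxplot(data, tick_labels=labels, showfliers=False)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_distance_heatmap(matrix: np.ndarray, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(matrix, cmap="viridis", origin="upper")
    fig.colorbar(im, ax=ax, shrink=0.85)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scatter(x, y, path, xlabel: str = "", ylabel: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(np.asarray(x), np.asarray(y), s=8, alpha=0.5)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
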