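"""Figures: embedding scatters, confusion heatmaps, sensitivity profiles."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_embedding(embedding, labels, ax=None, title=None):
    """2-D or 3-D scatter of embedded trials, one colour per class."""
    coords = embedding.coords
    labels = np.asarray(labels)
    classes = np.unique(labels)
    cmap = plt.get_cmap("tab20" if classes.size > 10 else "tab10")
    if ax is None:
        fig = plt.figure(figsize=(7, 6))
        ax = fig.add_subplot(111, projection="3d" if coords.shape[1] == 3 else None)
    for i, c in enumerate(classes):
        pts = coords[labels == c]
        ax.scatter(*pts.T, s=14, color=cmap(i % cmap.N), label=str(c))
    if classes.size <= 12:
        ax.legend(fontsize=7, loc="best")
    ax.set_title(title or f"t-SNE embedding (perplexity {embedding.perplexity:g})")
    return ax


def plot_confusion(report, ax=None, title="Confusion matrix"):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(report.confusion, cmap="viridis")
    ax.figure.colorbar(im, ax=ax, label="trials")
    labels = [str(c) for c in report.class_order]
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(labels)), labels, fontsize=6)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(title)
    return ax


def plot_size_profile(profile, ax=None, title="Quality of clustering vs number of features"):
    """Max/mean/min clustering quality against subset size."""
    t = profile.table
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(t["size"], t["max"], "o-", label="max")
    ax.plot(t["size"], t["mean"], "s-", label="mean")
    ax.plot(t["size"], t["min"], "v-", label="min")
    ax.set_xlabel("number of features kept")
    ax.set_ylabel("cross-validated accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend()
    ax.set_title(title)
    return ax


def plot_time_windows(window_table, ax=None, title="Quality per retained time window"):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    centers = (window_table["start"] + window_table["stop"]) / 2
    ax.bar(centers, window_table["quality"],
           width=(window_table["stop"] - window_table["start"]) * 0.9)
    ax.set_xlabel("time-normalized sample")
    ax.set_ylabel("cross-validated accuracy")
    ax.set_title(title)
    return ax


def savefig(ax, path):
    ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(ax.figure)
    return path
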