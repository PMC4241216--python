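"""Figure rendering: dendrogram, validity curves, factor maps, 3-D tree."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from scipy.cluster.hierarchy import dendrogram  # noqa: E402

from .cluster import MergeTree  # noqa: E402
from .hcpc import HCPCView  # noqa: E402
from .pca import PCAResult, correlation_circle  # noqa: E402
from .validity import ValidityProfile  # noqa: E402

__all__ = [
    "plot_dendrogram",
    "plot_validity_profile",
    "plot_correlation_circle",
    "plot_object_map",
    "plot_hcpc_tree",
]


def _save(fig, path):
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_dendrogram(tree: MergeTree, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 5))
    dendrogram(tree.to_scipy(), labels=tree.labels, ax=ax, leaf_rotation=90)
    ax.set_ylabel(f"{tree.linkage} linkage height ({tree.metric})")
    ax.set_title("Hierarchical tree of management objects")
    _save(fig, path)


def plot_validity_profile(profile: ValidityProfile, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    t = profile.table
    for col, style in (
        ("RSQ", "o-"),
        ("SPRSQ", "s-"),
        ("RMSSTD", "d-"),
        ("pF_scaled", "^-"),
    ):
        ax.plot(t.index, t[col], style, label="pF (scaled)" if col == "pF_scaled" else col)
    ax.axvline(profile.suggested_k, color="grey", ls=":", label=f"suggested k = {profile.suggested_k}")
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("index value")
    ax.set_title("Determination of the optimal number of clusters")
    ax.legend(fontsize=8)
    _save(fig, path)


def plot_correlation_circle(pca: PCAResult, path: str | Path, threshold: float = 0.8) -> None:
    circ = correlation_circle(pca, threshold=threshold)
    fig, ax = plt.subplots(figsize=(6.5, 6.5))
    theta = np.linspace(0, 2 * np.pi, 200)
    ax.plot(np.cos(theta), np.sin(theta), "k-", lw=0.8)
    ax.plot(threshold * np.cos(theta), threshold * np.sin(theta), "r-", lw=0.8)
    for label, row in circ.iterrows():
        color = "tab:red" if row["flagged"] else "tab:blue"
        ax.annotate(
            label,
            (row["phi1"], row["phi2"]),
            fontsize=7,
            color=color,
            ha="center",
        )
        ax.plot([0, row["phi1"]], [0, row["phi2"]], color=color, lw=0.6, alpha=0.6)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_aspect("equal")
    pct = pca.proportions * 100
    ax.set_xlabel(f"F1 ({pct[0]:.1f}%)")
    ax.set_ylabel(f"F2 ({pct[1]:.1f}%)")
    ax.set_title("Areas of variability in the correlation circle")
    _save(fig, path)


def plot_object_map(pca: PCAResult, path: str | Path, labels=None) -> None:
    fig, ax = plt.subplots(figsize=(7, 6))
    xy = pca.psi.iloc[:, :2].to_numpy()
    colors = None
    if labels is not None:
        labels = np.asarray(labels)
        cmap = plt.get_cmap("tab10")
        colors = [cmap(int(l) % 10) for l in labels]
    ax.scatter(xy[:, 0], xy[:, 1], c=colors, s=40)
    for i, name in enumerate(pca.object_labels):
        ax.annotate(name, xy[i], fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    pct = pca.proportions * 100
    ax.set_xlabel(f"F1 ({pct[0]:.1f}%)")
    ax.set_ylabel(f"F2 ({pct[1]:.1f}%)")
    ax.set_title("Objects on the first factorial plane")
    _save(fig, path)


def plot_hcpc_tree(view: HCPCView, path: str | Path) -> None:
    fig = plt.figure(figsize=(8, 6))
    ax = fig.add_subplot(projection="3d")
    for (x0, y0, z0), (x1, y1, z1) in view.segments:
        ax.plot([x0, x1], [y0, y1], [z0, z1], color="tab:blue", lw=0.9)
    xy = view.coords.to_numpy()
    cmap = plt.get_cmap("tab10")
    colors = [cmap(int(l) % 10) for l in view.labels]
    ax.scatter(xy[:, 0], xy[:, 1], np.zeros(len(xy)), c=colors, s=35)
    for i, name in enumerate(view.coords.index):
        ax.text(xy[i, 0], xy[i, 1], 0, str(name), fontsize=6)
    ax.set_xlabel("F1")
    ax.set_ylabel("F2")
    ax.set_zlabel("merge height")
    ax.set_title(f"Hierarchical tree over the factor map (k = {view.k})")
    _save(fig, path)
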