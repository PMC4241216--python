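"""Hierarchical clustering on the principal-component map, and reporting.

The selected dendrogram is drawn in three dimensions over the first
factorial plane: leaves sit at their (F1, F2) coordinates at height 0,
every internal node at the center of gravity of its member objects, raised
to its merge height.  The integrated report collects the model selection,
the validity profile, the cluster memberships and the PCA diagnostics into
one structured document.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import CombinationScan, MergeTree, cut
from .pca import PCAResult, correlation_circle, ctr_individuals, ctr_variables
from .validity import ValidityProfile

__all__ = ["HCPCView", "Report", "embed_tree", "interpretation_report"]


@dataclass
class HCPCView:
    """Drawable 3-D embedding of a merge tree over the factor map."""

    coords: pd.DataFrame          # m x 2 leaf coordinates (F1, F2)
    labels: np.ndarray            # cluster label per object at the chosen k
    k: int
    node_xy: dict[int, tuple[float, float]]   # node id -> plane position
    node_height: dict[int, float]             # node id -> z
    segments: list[tuple[tuple[float, float, float], tuple[float, float, float]]]


def embed_tree(tree: MergeTree, pca: PCAResult, k: int) -> HCPCView:
    """Project the tree onto the first two principal axes.

    Requires the tree and the PCA to come from the same matrix (matching
    object labels).  Each internal node's plane position is the mean of its
    member leaves' coordinates; its height is the merge height.
    """
    if list(tree.labels) != list(pca.object_labels):
        raise ValueError("tree and PCA were built from different object sets")
    m = tree.n_leaves
    coords = pca.psi.iloc[:, :2].copy()
    xy = coords.to_numpy()
    node_xy: dict[int, tuple[float, float]] = {
        i: (float(xy[i, 0]), float(xy[i, 1])) for i in range(m)
    }
    node_height: dict[int, float] = {i: 0.0 for i in range(m)}
    members = tree.members()
    segments = []
    for step, (left, right, h, _) in enumerate(tree.steps):
        node = m + step
        mem = members[node]
        cx, cy = xy[mem].mean(axis=0)
        node_xy[node] = (float(cx), float(cy))
        node_height[node] = float(h)
        for child in (int(left), int(right)):
            x0, y0 = node_xy[child]
            segments.append(
                ((x0, y0, node_height[child]), (float(cx), float(cy), float(h)))
            )
    return HCPCView(
        coords=coords,
        labels=cut(tree, k),
        k=k,
        node_xy=node_xy,
        node_height=node_height,
        segments=segments,
    )


@dataclass
class Report:
    body: dict

    def to_dict(self) -> dict:
        return self.body

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.body, indent=2, sort_keys=True, **kwargs)

    def to_markdown(self) -> str:
        b = self.body
        lines = [
            "# Cost-variability analysis report",
            "",
            "## Model selection",
            f"Best combination: **{b['best_linkage']} linkage, "
            f"{b['best_metric']} distance** "
            f"(cophenetic correlation c = {b['best_coefficient']:.5f})",
            "",
            "## Number of clusters",
            f"Suggested k = {b['suggested_k']} (pseudo-F peak)",
            "",
            "## Cluster memberships",
        ]
        for cl in b["clusters"]:
            names = ", ".join(cl["members"])
            lines.append(f"- cluster {cl['node']}: {names}")
        lines += ["", "## Principal components"]
        lines.append(
            "Cumulative inertia: "
            + ", ".join(
                f"{a + 1} axes {v:.2f}%" for a, v in enumerate(b["cumulative_inertia"])
            )
        )
        lines.append(f"Kaiser retention (eigenvalues > 1): {b['kaiser_count']}")
        for ax in b["axes"]:
            lines.append(
                f"- axis {ax['axis']}: top objects {', '.join(ax['top_objects'])}; "
                f"top areas {', '.join(ax['top_areas'])}"
            )
        flagged = ", ".join(b["well_represented_areas"]) or "none"
        lines.append(f"Well-represented areas (r_j >= 0.8): {flagged}")
        return "\n".join(lines) + "\n"


def interpretation_report(
    scan: CombinationScan,
    profile: ValidityProfile,
    pca: PCAResult,
    view: HCPCView,
    n_axes: int = 2,
    ctr_threshold: float | None = None,
) -> Report:
    """Assemble the integrated interpretation of all four stages.

    "Strong" contributors are those whose CTR exceeds the uniform share
    (1/m for objects, 1/n for areas) unless ``ctr_threshold`` overrides it.
    Raises ``ValueError`` listing the missing stages when any input is None.
    """
    missing = [
        name
        for name, value in (
            ("scan", scan),
            ("profile", profile),
            ("pca", pca),
            ("view", view),
        )
        if value is None
    ]
    if missing:
        raise ValueError(f"stages not run: {', '.join(missing)}")

    tree = scan.best_tree
    m = tree.n_leaves
    labels = view.labels
    members_by_node = tree.members()
    numbers = tree.node_numbers()

    # paper-style node number for each flat cluster: the highest node whose
    # member set equals the cluster (leaf number for singletons)
    clusters = []
    for lab in sorted(set(labels)):
        mem = sorted(int(i) for i in np.where(labels == lab)[0])
        node_id = mem[0]
        for nid in range(m, 2 * m - 1):
            if sorted(members_by_node[nid]) == mem:
                node_id = nid
        clusters.append(
            {
                "label": int(lab),
                "node": numbers[node_id],
                "members": [tree.labels[i] for i in mem],
            }
        )

    obj_thr = ctr_threshold if ctr_threshold is not None else 1.0 / m
    area_thr = ctr_threshold if ctr_threshold is not None else 1.0 / len(pca.area_labels)
    axes = []
    for axis in range(1, n_axes + 1):
        ci = ctr_individuals(pca, axis)
        cv = ctr_variables(pca, axis)
        axes.append(
            {
                "axis": axis,
                "top_objects": list(ci[ci > obj_thr].sort_values(ascending=False).index),
                "top_areas": list(cv[cv > area_thr].sort_values(ascending=False).index),
            }
        )

    circle = correlation_circle(pca)
    body = {
        "best_metric": scan.best_metric,
        "best_linkage": scan.best_linkage,
        "best_coefficient": round(float(scan.best_coefficient), 12),
        "scan": [
            {
                "metric": r.metric,
                "linkage": r.linkage,
                "coefficient": None if pd.isna(r.coefficient) else round(float(r.coefficient), 12),
            }
            for r in scan.table.itertuples()
        ],
        "suggested_k": int(profile.suggested_k),
        "validity": {
            str(k): {c: round(float(v), 12) for c, v in row.items()}
            for k, row in profile.table.iterrows()
        },
        "clusters": clusters,
        "cumulative_inertia": [
            round(float(pca.cumulative_inertia(a + 1)), 12) for a in range(n_axes + 1)
        ],
        "kaiser_count": pca.kaiser_count(),
        "axes": axes,
        "well_represented_areas": list(circle[circle["flagged"]].index),
    }
    return Report(body=body)
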