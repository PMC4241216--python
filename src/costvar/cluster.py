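"""Agglomerative hierarchical clustering with cophenetic model selection.

Five linkage criteria are supported.  Single, complete and average linkage
are driven by the pairwise object distances through Lance-Williams updates;
centroid and Ward linkage are recomputed from cluster centroids, so that
they remain well defined (if unconventional) under non-Euclidean metrics —
the full model-selection scan evaluates all 3 metrics x 5 linkages and
keeps the combination whose dendrogram best preserves the original
distances, as measured by the cophenetic correlation coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .distances import (
    METRICS,
    DistanceMatrix,
    compute_distances,
)
from .model import StandardizedMatrix

__all__ = [
    "LINKAGES",
    "MergeTree",
    "CopheneticResult",
    "CombinationScan",
    "DegenerateInputError",
    "agglomerate",
    "cophenetic_distances",
    "cophenetic_coefficient",
    "scan_combinations",
    "cut",
]

LINKAGES = ("single", "complete", "average", "centroid", "ward")


class DegenerateInputError(ValueError):
    """Raised when a correlation is requested on constant distances."""


@dataclass
class MergeTree:
    """Sequence of m-1 agglomeration steps.

    ``steps`` follows the scipy convention: row ``i`` holds
    ``(left_id, right_id, height, size)`` where leaves are ``0..m-1`` and the
    cluster formed at step ``i`` has id ``m+i``.  Heights are the
    inter-cluster criterion value at the merge (for Ward, in squared-distance
    units).
    """

    steps: np.ndarray
    linkage: str
    metric: str
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return self.steps.shape[0] + 1

    @property
    def heights(self) -> np.ndarray:
        return self.steps[:, 2]

    @property
    def is_monotone(self) -> bool:
        return not self.inversions()

    def inversions(self) -> list[int]:
        """Indices of merges lower than an earlier merge (centroid only)."""
        h = self.heights
        return [i for i in range(1, len(h)) if h[i] < h[i - 1] - 1e-12]

    def members(self) -> list[list[int]]:
        """Leaf members of every node, indexed by node id (0..2m-2)."""
        m = self.n_leaves
        out: list[list[int]] = [[i] for i in range(m)]
        for left, right, _, _ in self.steps:
            out.append(out[int(left)] + out[int(right)])
        return out

    def node_numbers(self) -> dict[int, int]:
        """1-based display numbering: leaves 1..m, new clusters m+1..2m-1."""
        return {i: i + 1 for i in range(2 * self.n_leaves - 1)}

    def cut(self, k: int) -> np.ndarray:
        return cut(self, k)

    def cophenetic_distances(self) -> np.ndarray:
        return cophenetic_distances(self)

    def to_scipy(self) -> np.ndarray:
        """Linkage array usable with scipy.cluster.hierarchy functions."""
        return self.steps.astype(float)

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        m = self.n_leaves
        height = {i: 0.0 for i in range(m)}
        text = {i: self.labels[i].replace(",", "_").replace("(", "_").replace(")", "_")
                for i in range(m)}
        for i, (left, right, h, _) in enumerate(self.steps):
            left, right = int(left), int(right)
            node = m + i
            parts = []
            for child in (left, right):
                bl = max(h - height[child], 0.0)
                parts.append(f"{text[child]}:{bl:.6g}")
            text[node] = f"({parts[0]},{parts[1]})"
            height[node] = h
        return text[2 * m - 2] + ";"

    def to_dict(self) -> dict:
        return {
            "linkage": self.linkage,
            "metric": self.metric,
            "labels": list(self.labels),
            "steps": [
                {"left": int(l), "right": int(r), "height": float(h), "size": int(s)}
                for l, r, h, s in self.steps
            ],
        }


@dataclass
class CopheneticResult:
    Y: np.ndarray
    Z: np.ndarray
    coefficient: float
    mean_y: float
    mean_z: float


@dataclass
class CombinationScan:
    """Cophenetic coefficient for every (metric, linkage) combination."""

    table: pd.DataFrame  # columns: metric, linkage, coefficient
    best_metric: str
    best_linkage: str
    best_coefficient: float
    trees: dict[tuple[str, str], MergeTree] = field(default_factory=dict)

    @property
    def best_tree(self) -> MergeTree:
        return self.trees[(self.best_metric, self.best_linkage)]


def _vector_metric(D: DistanceMatrix):
    """Distance between two vectors under the matrix's metric."""
    if D.metric == "euclidean":
        return lambda a, b: float(np.linalg.norm(a - b))
    if D.metric == "cityblock":
        return lambda a, b: float(np.abs(a - b).sum())
    if D.metric == "mahalanobis":
        VI = D.inverse_covariance
        if VI is None:
            raise ValueError("Mahalanobis distance matrix lacks its inverse covariance")

        def dist(a, b):
            d = a - b
            return float(np.sqrt(max(d @ VI @ d, 0.0)))

        return dist
    raise ValueError(f"unknown metric {D.metric!r}")


# Lance-Williams coefficients (alpha_r, alpha_s, beta, gamma) for the
# distance-update d(t, u) = a_r d(r,u) + a_s d(s,u) + b d(r,s) + g |d(r,u)-d(s,u)|
def _lw_coeffs(linkage: str, nr: int, ns: int, nu: int):
    if linkage == "single":
        return 0.5, 0.5, 0.0, -0.5
    if linkage == "complete":
        return 0.5, 0.5, 0.0, 0.5
    if linkage == "average":
        return nr / (nr + ns), ns / (nr + ns), 0.0, 0.0
    raise ValueError(linkage)


def agglomerate(
    D: DistanceMatrix,
    linkage: str,
    X: StandardizedMatrix | np.ndarray | None = None,
) -> MergeTree:
    """Build the full merge tree under the given linkage criterion.

    Single/complete/average operate on the pairwise distances (via
    Lance-Williams updates).  Centroid linkage merges the pair with the
    closest centroids d(xbar_r, xbar_s); Ward merges the pair minimising
    (n_r n_s)/(n_r + n_s) * d^2(xbar_r, xbar_s), the incremental
    within-group sum of squares.  Both therefore need the data matrix X.
    Ties are broken toward the lexicographically smallest (small id,
    large id) pair of cluster ids.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")
    m = D.frame.shape[0]
    if m < 2:
        raise ValueError("at least 2 objects are required")
    needs_data = linkage in ("centroid", "ward")
    if needs_data:
        if X is None:
            raise ValueError(f"{linkage} linkage requires the data matrix X")
        if D.metric != "euclidean":
            warnings.warn(
                f"{linkage} linkage is defined through centroids; with the "
                f"{D.metric} metric the result is heuristic",
                stacklevel=2,
            )
        arr = X.values if isinstance(X, StandardizedMatrix) else np.asarray(X, float)
        if arr.shape[0] != m:
            raise ValueError("X and D disagree on the number of objects")
        vdist = _vector_metric(D)

    sq = D.values.astype(float).copy()
    active: dict[int, dict] = {
        i: {"size": 1, "members": [i]} for i in range(m)
    }
    if needs_data:
        for i in range(m):
            active[i]["centroid"] = arr[i].astype(float)
    # working pairwise criterion between active clusters, keyed by (id, id)
    crit: dict[tuple[int, int], float] = {}
    for i in range(m):
        for j in range(i + 1, m):
            crit[(i, j)] = sq[i, j]
    if needs_data:
        for i, j in list(crit):
            d = vdist(active[i]["centroid"], active[j]["centroid"])
            crit[(i, j)] = 0.5 * d * d if linkage == "ward" else d

    steps = np.zeros((m - 1, 4))
    next_id = m
    for step in range(m - 1):
        # minimal pair; lexicographic tie-break on sorted ids
        best_pair, best_val = None, np.inf
        for pair in sorted(crit):
            v = crit[pair]
            if v < best_val:
                best_val, best_pair = v, pair
        r, s = best_pair
        nr, ns = active[r]["size"], active[s]["size"]
        new = {
            "size": nr + ns,
            "members": active[r]["members"] + active[s]["members"],
        }
        if needs_data:
            new["centroid"] = (
                nr * active[r]["centroid"] + ns * active[s]["centroid"]
            ) / (nr + ns)
        steps[step] = (r, s, best_val, nr + ns)

        others = [t for t in active if t not in (r, s)]
        for t in others:
            key_rt = (min(r, t), max(r, t))
            key_st = (min(s, t), max(s, t))
            if needs_data:
                d = vdist(new["centroid"], active[t]["centroid"])
                if linkage == "centroid":
                    val = d
                else:  # ward
                    nt = active[t]["size"]
                    val = (new["size"] * nt) / (new["size"] + nt) * d * d
            else:
                ar, as_, b, g = _lw_coeffs(linkage, nr, ns, active[t]["size"])
                drt, dst = crit[key_rt], crit[key_st]
                val = ar * drt + as_ * dst + b * best_val + g * abs(drt - dst)
            del crit[key_rt], crit[key_st]
            crit[(min(next_id, t), max(next_id, t))] = val
        del crit[best_pair]
        del active[r], active[s]
        active[next_id] = new
        next_id += 1

    return MergeTree(steps=steps, linkage=linkage, metric=D.metric, labels=D.labels)


def cophenetic_distances(tree: MergeTree) -> np.ndarray:
    """Condensed matrix Z: height of the lowest merge joining each pair."""
    m = tree.n_leaves
    Z = np.zeros((m, m))
    members = [[i] for i in range(m)]
    for left, right, h, _ in tree.steps:
        lm, rm = members[int(left)], members[int(right)]
        for i in lm:
            for j in rm:
                Z[i, j] = Z[j, i] = h
        members.append(lm + rm)
    return squareform(Z, checks=False)


def cophenetic_coefficient(Y: np.ndarray, Z: np.ndarray) -> float:
    """Pearson-type correlation between original and cophenetic distances.

    c = sum (Y_ij - y)(Z_ij - z) / sqrt( sum (Y_ij - y)^2 sum (Z_ij - z)^2 )
    """
    Y = np.asarray(Y, float).ravel()
    Z = np.asarray(Z, float).ravel()
    if Y.shape != Z.shape:
        raise ValueError("Y and Z must have the same length")
    if Y.size < 2:
        raise DegenerateInputError(
            "fewer than 2 pairwise distances: coefficient undefined"
        )
    y, z = Y.mean(), Z.mean()
    dy, dz = Y - y, Z - z
    denom = np.sqrt((dy**2).sum() * (dz**2).sum())
    if denom == 0.0:
        raise DegenerateInputError("constant distance vector: coefficient undefined")
    return float((dy * dz).sum() / denom)


def cophenetic(tree: MergeTree, D: DistanceMatrix) -> CopheneticResult:
    """Convenience wrapper pairing a tree with its source distances."""
    Y = D.condensed()
    Z = cophenetic_distances(tree)
    return CopheneticResult(
        Y=Y, Z=Z, coefficient=cophenetic_coefficient(Y, Z),
        mean_y=float(Y.mean()), mean_z=float(Z.mean()),
    )


def scan_combinations(
    X: StandardizedMatrix,
    metrics=METRICS,
    linkages=LINKAGES,
) -> CombinationScan:
    """Evaluate the cophenetic coefficient for every metric x linkage pair.

    Degenerate combinations (constant distances) are recorded as NaN rather
    than aborting the scan.  The best pair attains the maximum coefficient;
    ties resolve to the first pair in listed order.
    """
    rows = []
    trees: dict[tuple[str, str], MergeTree] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # centroid/ward under non-Euclidean metrics
        for metric in metrics:
            D = compute_distances(X, metric)
            for link in linkages:
                try:
                    tree = agglomerate(D, link, X=X)
                    c = cophenetic_coefficient(D.condensed(), cophenetic_distances(tree))
                    trees[(metric, link)] = tree
                except DegenerateInputError:
                    c = np.nan
                rows.append({"metric": metric, "linkage": link, "coefficient": c})
    table = pd.DataFrame(rows)
    if table["coefficient"].isna().all():
        raise DegenerateInputError("all metric/linkage combinations are degenerate")
    best = table.loc[table["coefficient"].idxmax()]
    return CombinationScan(
        table=table,
        best_metric=str(best["metric"]),
        best_linkage=str(best["linkage"]),
        best_coefficient=float(best["coefficient"]),
        trees=trees,
    )


def cut(tree: MergeTree, k: int) -> np.ndarray:
    """Partition into k clusters by undoing the k-1 last (highest) merges.

    Returns integer labels 1..k, numbered by each cluster's smallest member
    index.  For monotone linkages the last merges are exactly the highest;
    under centroid inversions the chronological rule keeps the cut
    deterministic and nested.
    """
    m = tree.n_leaves
    if not 1 <= k <= m:
        raise ValueError(f"k must lie in [1, {m}]")
    parent = list(range(m))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    members = [[i] for i in range(m)]
    for left, right, _, _ in tree.steps[: m - k]:
        lm, rm = members[int(left)], members[int(right)]
        root = find(lm[0])
        for j in rm:
            parent[find(j)] = root
        members.append(lm + rm)
    roots: dict[int, int] = {}
    labels = np.zeros(m, dtype=int)
    for i in range(m):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[i] = roots[r]
    return labels
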