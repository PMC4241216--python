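"""Sums-of-squares indices for choosing the number of clusters.

RSQ measures the heterogeneity of a partition (between-cluster share of the
total sum of squares); SPRSQ the loss of homogeneity caused by a single
merge; RMSSTD the compactness of a newly formed cluster; and the pseudo-F
statistic (Calinski-Harabasz form) the ratio of between- to within-cluster
mean squares.  All are computed on the standardized matrix X, the space in
which the clusters were formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import MergeTree, cut
from .model import StandardizedMatrix

__all__ = [
    "ValidityProfile",
    "rsq",
    "sprsq",
    "rmsstd",
    "pseudo_f",
    "validity_profile",
    "suggest_k",
]


def _arr(X) -> np.ndarray:
    if isinstance(X, StandardizedMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _ssw(arr: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        block = arr[labels == lab]
        total += float(((block - block.mean(axis=0)) ** 2).sum())
    return total


def _sst(arr: np.ndarray) -> float:
    return float(((arr - arr.mean(axis=0)) ** 2).sum())


def rsq(X, labels) -> float:
    """1 - SSW/SST: share of total sum of squares explained by the partition."""
    arr = _arr(X)
    labels = np.asarray(labels)
    if labels.shape[0] != arr.shape[0] or labels.size == 0:
        raise ValueError("labels must assign every row to a cluster")
    sst = _sst(arr)
    if sst == 0.0:
        raise ValueError("total sum of squares is zero")
    return 1.0 - _ssw(arr, labels) / sst


def sprsq(X, tree: MergeTree, step: int) -> float:
    """SSW increase caused by merge ``step`` (0-based), as a share of SST."""
    arr = _arr(X)
    members = tree.members()
    left, right = int(tree.steps[step, 0]), int(tree.steps[step, 1])
    lm, rm = members[left], members[right]
    a, b = arr[lm], arr[rm]
    merged = arr[lm + rm]

    def ss(block):
        return float(((block - block.mean(axis=0)) ** 2).sum())

    return (ss(merged) - ss(a) - ss(b)) / _sst(arr)


def rmsstd(X, members) -> float:
    """Pooled standard deviation of a cluster: sqrt(SS / (n_vars * (n-1))).

    Returns 0 for singletons by convention.
    """
    arr = _arr(X)
    members = list(members)
    if len(members) <= 1:
        return 0.0
    block = arr[members]
    ss = float(((block - block.mean(axis=0)) ** 2).sum())
    return float(np.sqrt(ss / (arr.shape[1] * (len(members) - 1))))


def pseudo_f(X, labels) -> float:
    """Calinski-Harabasz statistic (SSB/(k-1)) / (SSW/(m-k)).

    Defined for 2 <= k < m; a zero within-cluster sum of squares yields
    ``inf`` (perfectly separated duplicates).
    """
    arr = _arr(X)
    labels = np.asarray(labels)
    m = arr.shape[0]
    k = len(np.unique(labels))
    if not 2 <= k < m:
        raise ValueError(f"pseudo-F requires 2 <= k < m (got k={k}, m={m})")
    sst = _sst(arr)
    ssw = _ssw(arr, labels)
    ssb = sst - ssw
    if ssw == 0.0:
        return float("inf")
    return (ssb / (k - 1)) / (ssw / (m - k))


@dataclass
class ValidityProfile:
    """Per-k table of RSQ, SPRSQ, RMSSTD, pseudo-F and the suggested k."""

    table: pd.DataFrame  # index k; columns RSQ, SPRSQ, RMSSTD, pF, pF_scaled
    suggested_k: int

    def __getitem__(self, k: int) -> pd.Series:
        return self.table.loc[k]


def validity_profile(
    tree: MergeTree,
    X,
    k_range: tuple[int, int] | None = None,
    rule: str = "first_peak",
) -> ValidityProfile:
    """Evaluate the four indices over cuts of the tree.

    For each k, SPRSQ belongs to the merge that *produced* the k-cluster
    solution and RMSSTD to the cluster formed by that merge.  pF is scaled
    to [0, 1] by its maximum over the profile so the four curves can share
    a plot.
    """
    arr = _arr(X)
    m = arr.shape[0]
    k_min, k_max = k_range if k_range is not None else (2, m - 1)
    if not 2 <= k_min <= k_max <= m - 1:
        raise ValueError(f"k range must satisfy 2 <= k_min <= k_max <= {m - 1}")
    members = tree.members()
    rows = {}
    for k in range(k_min, k_max + 1):
        labels = cut(tree, k)
        step = m - 1 - k  # the merge going from k+1 to k clusters
        new_members = members[m + step]
        rows[k] = {
            "RSQ": rsq(arr, labels),
            "SPRSQ": sprsq(arr, tree, step),
            "RMSSTD": rmsstd(arr, new_members),
            "pF": pseudo_f(arr, labels),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "k"
    pf = table["pF"].to_numpy()
    finite = pf[np.isfinite(pf)]
    peak = finite.max() if finite.size else 1.0
    table["pF_scaled"] = np.where(np.isfinite(pf), pf / peak, 1.0)
    profile = ValidityProfile(table=table, suggested_k=0)
    profile.suggested_k = suggest_k(profile, rule=rule)
    return profile


def suggest_k(profile: ValidityProfile, rule: str = "first_peak") -> int:
    """Number of clusters suggested by the pseudo-F curve.

    ``rule="first_peak"`` returns the smallest k that is a local maximum of
    pF (peaks on the curve mark suitable partitions); ``rule="max"`` returns
    the global argmax.  Ties break toward smaller k.
    """
    pf = profile.table["pF"]
    ks = list(pf.index)
    if rule == "max":
        return int(pf.idxmax())
    if rule != "first_peak":
        raise ValueError(f"unknown rule {rule!r}")
    for i, k in enumerate(ks):
        left_ok = i == 0 or pf.iloc[i] >= pf.iloc[i - 1]
        right_ok = i == len(ks) - 1 or pf.iloc[i] > pf.iloc[i + 1]
        if left_ok and right_ok:
            return int(k)
    return int(pf.idxmax())
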