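"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: agglomeration is
done by recomputing each linkage criterion from the set definitions at
every step, and the validity indices are evaluated with explicit loops.
"""

from __future__ import annotations

import numpy as np


def brute_agglomerate(D: np.ndarray, linkage: str, X: np.ndarray | None = None):
    """Exhaustive-pair agglomeration from the set-based linkage definitions.

    Returns a list of (left_id, right_id, height, size) with the same id
    convention as the package (leaves 0..m-1, merges m..2m-2).
    """
    m = D.shape[0]
    clusters = {i: [i] for i in range(m)}
    steps = []
    next_id = m
    for _ in range(m - 1):
        best = None
        for r in sorted(clusters):
            for s in sorted(clusters):
                if s <= r:
                    continue
                a, b = clusters[r], clusters[s]
                cross = [D[i, j] for i in a for j in b]
                if linkage == "single":
                    val = min(cross)
                elif linkage == "complete":
                    val = max(cross)
                elif linkage == "average":
                    val = sum(cross) / len(cross)
                elif linkage == "centroid":
                    val = float(np.linalg.norm(X[a].mean(0) - X[b].mean(0)))
                elif linkage == "ward":
                    d = float(np.linalg.norm(X[a].mean(0) - X[b].mean(0)))
                    val = len(a) * len(b) / (len(a) + len(b)) * d * d
                else:
                    raise ValueError(linkage)
                if best is None or val < best[0]:
                    best = (val, r, s)
        val, r, s = best
        steps.append((r, s, val, len(clusters[r]) + len(clusters[s])))
        clusters[next_id] = clusters.pop(r) + clusters.pop(s)
        next_id += 1
    return steps


def brute_ssw(X: np.ndarray, labels) -> float:
    total = 0.0
    for lab in set(labels):
        rows = [i for i, l in enumerate(labels) if l == lab]
        centroid = X[rows].mean(axis=0)
        for i in rows:
            total += float(((X[i] - centroid) ** 2).sum())
    return total


def brute_rsq(X: np.ndarray, labels) -> float:
    grand = X.mean(axis=0)
    sst = float(((X - grand) ** 2).sum())
    return 1.0 - brute_ssw(X, labels) / sst


def brute_pseudo_f(X: np.ndarray, labels) -> float:
    m = X.shape[0]
    k = len(set(labels))
    grand = X.mean(axis=0)
    sst = float(((X - grand) ** 2).sum())
    ssw = brute_ssw(X, labels)
    return ((sst - ssw) / (k - 1)) / (ssw / (m - k))


def brute_rmsstd(X: np.ndarray, members) -> float:
    members = list(members)
    if len(members) <= 1:
        return 0.0
    block = X[members]
    ss = float(((block - block.mean(axis=0)) ** 2).sum())
    return float(np.sqrt(ss / (X.shape[1] * (len(members) - 1))))
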