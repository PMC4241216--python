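"""Pairwise object distances: standardized Euclidean, Mahalanobis, city-block.

Distances are computed between the rows of the standardized matrix X.  For
the Mahalanobis distance the sample covariance V of X is singular whenever
there are at least as many areas as objects (the usual case, e.g. 12 x 16);
a Moore-Penrose pseudo-inverse is then used and recorded on the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .model import StandardizedMatrix

__all__ = [
    "DistanceMatrix",
    "euclidean_distances",
    "mahalanobis_distances",
    "cityblock_distances",
    "METRICS",
]

METRICS = ("euclidean", "mahalanobis", "cityblock")

_RCOND = 1e-10  # relative rank tolerance for the pseudo-inverse


@dataclass
class DistanceMatrix:
    """Symmetric m x m distance matrix with zero diagonal."""

    metric: str
    frame: pd.DataFrame
    covariance: np.ndarray | None = None
    inverse_covariance: np.ndarray | None = None
    inversion: str | None = None  # "inverse" | "pseudo-inverse"

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def labels(self) -> list[str]:
        return list(self.frame.index)

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy condensed order."""
        return squareform(self.values, checks=False)


def _as_array(X: StandardizedMatrix | pd.DataFrame | np.ndarray):
    if isinstance(X, StandardizedMatrix):
        frame = X.frame
    elif isinstance(X, pd.DataFrame):
        frame = X
    else:
        arr = np.asarray(X, dtype=float)
        frame = pd.DataFrame(arr, index=[str(i + 1) for i in range(arr.shape[0])])
    if frame.shape[0] < 2:
        raise ValueError("at least 2 rows are required to compute distances")
    return frame.to_numpy(dtype=float), list(frame.index.astype(str))


def _wrap(metric: str, D: np.ndarray, labels, **extra) -> DistanceMatrix:
    frame = pd.DataFrame(squareform(D, checks=False), index=labels, columns=labels)
    return DistanceMatrix(metric=metric, frame=frame, **extra)


def euclidean_distances(X) -> DistanceMatrix:
    """d_rs = sqrt((x_r - x_s)(x_r - x_s)')."""
    arr, labels = _as_array(X)
    return _wrap("euclidean", pdist(arr, "euclidean"), labels)


def cityblock_distances(X) -> DistanceMatrix:
    """d_rs = sum_j |x_rj - x_sj|."""
    arr, labels = _as_array(X)
    return _wrap("cityblock", pdist(arr, "cityblock"), labels)


def mahalanobis_distances(X) -> DistanceMatrix:
    """d_rs^2 = (x_r - x_s)' V^- (x_r - x_s), V the sample covariance of X.

    V uses the 1/(m-1) denominator.  When V is rank deficient the
    Moore-Penrose pseudo-inverse (relative tolerance 1e-10) replaces the
    inverse; the result records which was used.
    """
    arr, labels = _as_array(X)
    V = np.cov(arr, rowvar=False, ddof=1)
    V = np.atleast_2d(V)
    rank = np.linalg.matrix_rank(V, tol=_RCOND * np.linalg.norm(V, 2))
    if rank == V.shape[0]:
        VI = np.linalg.inv(V)
        inversion = "inverse"
    else:
        VI = np.linalg.pinv(V, rcond=_RCOND)
        inversion = "pseudo-inverse"
    diffs = arr[:, None, :] - arr[None, :, :]
    d2 = np.einsum("ijk,kl,ijl->ij", diffs, VI, diffs)
    d2 = np.maximum(d2, 0.0)  # clip tiny negatives from the pseudo-inverse
    D = squareform(np.sqrt(d2), checks=False)
    return _wrap(
        "mahalanobis",
        D,
        labels,
        covariance=V,
        inverse_covariance=VI,
        inversion=inversion,
    )


_METRIC_FUNCS = {
    "euclidean": euclidean_distances,
    "mahalanobis": mahalanobis_distances,
    "cityblock": cityblock_distances,
}


def compute_distances(X, metric: str) -> DistanceMatrix:
    """Dispatch on metric name."""
    try:
        return _METRIC_FUNCS[metric](X)
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}") from None
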