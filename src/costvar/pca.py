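"""PCA of the standardized object x area matrix, with interpretive statistics.

The correlation matrix Gamma = (1/m) X'X is diagonalized.  Because the
columns of X are standardized, Gamma is the correlation matrix of the
areas, its trace equals the number of areas, and Kaiser's eigenvalue > 1
retention rule is meaningful.  Individuals (objects) are described by their
factor coordinates psi_a = X u_a and contributions CTR_a(i); variables
(areas) by their loadings phi_a(j) — the correlation between area j and
factor a — contributions CTR_a(j), representation qualities cos2_a(j) and
the distance r_j from the origin of the correlation circle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import StandardizedMatrix

__all__ = [
    "PCAResult",
    "fit_pca",
    "ctr_individuals",
    "ctr_variables",
    "cos2_variables",
    "correlation_circle",
    "kaiser_count",
]

_EIG_TOL = 1e-10


@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # descending, correlation scale
    proportions: np.ndarray          # eigenvalue shares of total inertia
    u: np.ndarray                    # n x n eigenvectors of Gamma (columns)
    v: np.ndarray                    # m x n unit vectors in individual space
    psi: pd.DataFrame                # m x n individual coordinates
    phi: pd.DataFrame                # n x n variable loadings (correlations)
    correlation: pd.DataFrame        # Gamma
    object_labels: list[str]
    area_labels: list[str]

    @property
    def rank(self) -> int:
        return int((self.eigenvalues > _EIG_TOL * self.eigenvalues[0]).sum())

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.proportions)

    def cumulative_inertia(self, n_axes: int) -> float:
        """Cumulative share of total inertia on the first axes, in percent."""
        return float(100.0 * self.proportions[:n_axes].sum())

    def kaiser_count(self) -> int:
        return kaiser_count(self)

    def correlation_circle(self, threshold: float = 0.8) -> pd.DataFrame:
        return correlation_circle(self, threshold=threshold)


def fit_pca(X: StandardizedMatrix | pd.DataFrame) -> PCAResult:
    """Eigendecomposition of the correlation matrix of X.

    The sign of each axis is fixed so that its largest-magnitude loading is
    positive; published factor maps are recoverable only up to reflection,
    so comparisons against them should ignore the global sign.
    """
    frame = X.frame if isinstance(X, StandardizedMatrix) else pd.DataFrame(X)
    arr = frame.to_numpy(dtype=float)
    m, n = arr.shape
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=0)
    if np.abs(means).max() > 1e-6 or np.abs(sds - 1.0).max() > 1e-6:
        raise ValueError(
            "fit_pca expects a standardized matrix (column mean 0, population s.d. 1)"
        )
    gamma = arr.T @ arr / m
    w, vec = np.linalg.eigh(gamma)
    order = np.argsort(w)[::-1]
    w = np.maximum(w[order], 0.0)
    u = vec[:, order]
    # deterministic sign: largest-|loading| positive per axis
    for a in range(n):
        j = int(np.argmax(np.abs(u[:, a])))
        if u[j, a] < 0:
            u[:, a] = -u[:, a]
    psi = arr @ u
    phi = u * np.sqrt(w)[None, :]
    v = np.zeros((m, n))
    for a in range(n):
        norm = np.sqrt(m * w[a])
        if norm > _EIG_TOL:
            v[:, a] = psi[:, a] / norm
    axes = [f"F{a + 1}" for a in range(n)]
    return PCAResult(
        eigenvalues=w,
        proportions=w / w.sum(),
        u=u,
        v=v,
        psi=pd.DataFrame(psi, index=frame.index, columns=axes),
        phi=pd.DataFrame(phi, index=frame.columns, columns=axes),
        correlation=pd.DataFrame(gamma, index=frame.columns, columns=frame.columns),
        object_labels=list(frame.index.astype(str)),
        area_labels=list(frame.columns.astype(str)),
    )


def _check_axis(result: PCAResult, axis: int) -> int:
    if not 1 <= axis <= result.eigenvalues.size:
        raise ValueError(f"axis must lie in [1, {result.eigenvalues.size}]")
    if result.eigenvalues[axis - 1] <= _EIG_TOL * max(result.eigenvalues[0], _EIG_TOL):
        raise ValueError(f"axis {axis} carries no variance")
    return axis - 1


def ctr_individuals(result: PCAResult, axis: int) -> pd.Series:
    """CTR_a(i) = psi_a(i)^2 / sum_i psi_a(i)^2 — object contributions."""
    a = _check_axis(result, axis)
    sq = result.psi.iloc[:, a] ** 2
    return sq / sq.sum()


def ctr_variables(result: PCAResult, axis: int) -> pd.Series:
    """CTR_a(j) = phi_a(j)^2 / sum_j phi_a(j)^2 — area contributions."""
    a = _check_axis(result, axis)
    sq = result.phi.iloc[:, a] ** 2
    return sq / sq.sum()


def cos2_variables(result: PCAResult, axis: int) -> pd.Series:
    """Quality of representation of each area on the axis.

    cos2_a(j) = phi_a(j)^2 / ||x_j||^2, with norms scaled so the qualities
    of a variable sum to 1 over all axes.
    """
    a = _check_axis(result, axis)
    norms = (result.phi**2).sum(axis=1)  # equals 1 for standardized columns
    return result.phi.iloc[:, a] ** 2 / norms


def correlation_circle(result: PCAResult, threshold: float = 0.8) -> pd.DataFrame:
    """Loadings on the first factorial plane, with r_j and the >= 0.8 flag.

    Rows are sorted in descending order of r_j = sqrt(phi_1^2 + phi_2^2),
    the distance of the variable point from the origin of the circle.
    """
    if result.eigenvalues.size < 2:
        raise ValueError("the correlation circle requires at least 2 axes")
    phi1 = result.phi.iloc[:, 0]
    phi2 = result.phi.iloc[:, 1]
    r = np.sqrt(phi1**2 + phi2**2)
    out = pd.DataFrame(
        {"phi1": phi1, "phi2": phi2, "r": r, "flagged": r >= threshold}
    )
    return out.sort_values("r", ascending=False)


def kaiser_count(result: PCAResult) -> int:
    """Number of eigenvalues strictly above 1 (correlation scale)."""
    return int((result.eigenvalues > 1.0).sum())
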