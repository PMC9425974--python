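"""Geometry of homogeneity distributions.

Family homogeneity profiles are smoothed with a Gaussian kernel along the
alignment, converted to probability densities on a fixed grid over [0, 1],
compared pairwise with the Hellinger distance, and embedded in the plane with
classical (Torgerson) multidimensional scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "SmoothedProfile",
    "HomogeneityDensity",
    "EmbeddingResult",
    "smooth_profile",
    "estimate_density",
    "hellinger_distance",
    "hellinger_matrix",
    "classical_mds",
    "DENSITY_GRID_SIZE",
]

#: Number of equidistant evaluation points on [0, 1] for density estimates.
DENSITY_GRID_SIZE = 101

DEFAULT_BANDWIDTH = 20.0


@dataclass
class SmoothedProfile:
    family_id: str
    h_smooth: np.ndarray
    bandwidth: float = DEFAULT_BANDWIDTH

    def __post_init__(self) -> None:
        self.h_smooth = np.asarray(self.h_smooth, dtype=float)


@dataclass
class HomogeneityDensity:
    """Unit-mass density of smoothed homogeneity values on the [0, 1] grid."""

    family_id: str
    grid: np.ndarray
    mass: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.grid.shape != self.mass.shape:
            raise ValueError("grid and mass differ in shape")
        if np.any(self.mass < 0):
            raise ValueError("density mass must be non-negative")
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("density mass must sum to 1")


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # (n_items, dims)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    ids: list[str] | None = None


def smooth_profile(
    h,
    b: float = DEFAULT_BANDWIDTH,
    family_id: str = "",
) -> SmoothedProfile:
    """Gaussian-kernel smoothing of a homogeneity profile along positions.

    ``h_i' = sum_j h_j K_ij / sum_j K_ij`` with ``K_ij = exp(-((j - i)/b)^2)``.
    The kernel is truncated at the profile ends; the normalization absorbs the
    edge effect.  NaN entries (masked columns) are excluded from both sums.
    """
    h = np.asarray(h, dtype=float)
    if h.size == 0:
        raise ValueError("empty profile")
    if b <= 0:
        raise ValueError("bandwidth must be positive")
    idx = np.arange(h.size)
    valid = ~np.isnan(h)
    if not valid.any():
        raise ValueError("profile has no scored values")
    # (i, j) kernel over valid positions only
    kernel = np.exp(-(((idx[None, :] - idx[:, None]) / b) ** 2))
    kernel[:, ~valid] = 0.0
    weights = kernel.sum(axis=1)
    smoothed = kernel @ np.where(valid, h, 0.0) / weights
    smoothed[~valid] = np.nan
    return SmoothedProfile(family_id=family_id, h_smooth=smoothed, bandwidth=b)


def estimate_density(
    sp: SmoothedProfile,
    grid_size: int = DENSITY_GRID_SIZE,
) -> HomogeneityDensity:
    """Gaussian KDE of the smoothed homogeneity values on the [0, 1] grid.

    Bandwidth follows Silverman's rule.  Mass leaking past the support
    boundaries is folded back by reflection at 0 and 1, and the grid vector is
    renormalized to unit mass.  If all values coincide (zero variance, where a
    KDE is undefined) the density degenerates to a unit spike at the nearest
    grid point.
    """
    values = np.asarray(sp.h_smooth, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 1:
        raise ValueError("no values to estimate a density from")
    grid = np.linspace(0.0, 1.0, grid_size)
    if values.size < 2 or np.ptp(values) == 0.0:
        mass = np.zeros(grid_size)
        mass[int(np.argmin(np.abs(grid - values.mean())))] = 1.0
        return HomogeneityDensity(
            sp.family_id, grid, mass, metadata={"estimator": "degenerate-spike"}
        )
    kde = gaussian_kde(values, bw_method="silverman")
    # Boundary reflection at 0 and 1 keeps mass on the supported interval.
    dens = kde(grid) + kde(-grid) + kde(2.0 - grid)
    mass = dens / dens.sum()
    return HomogeneityDensity(
        sp.family_id,
        grid,
        mass,
        metadata={"estimator": "gaussian-kde-silverman-reflected"},
    )


def hellinger_distance(p: HomogeneityDensity, q: HomogeneityDensity) -> float:
    """Discrete Hellinger distance ``sqrt(1 - sum_i sqrt(p_i q_i))`` in [0, 1]."""
    if p.grid.shape != q.grid.shape or not np.allclose(p.grid, q.grid):
        raise ValueError("densities are defined on different grids")
    bc = float(np.sqrt(p.mass * q.mass).sum())
    return float(np.sqrt(max(1.0 - min(bc, 1.0), 0.0)))


def hellinger_matrix(densities: list[HomogeneityDensity]) -> np.ndarray:
    """Symmetric matrix of pairwise Hellinger distances."""
    n = len(densities)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = hellinger_distance(densities[i], densities[j])
    return d


def classical_mds(
    dist: np.ndarray,
    dims: int = 2,
    ids: list[str] | None = None,
) -> EmbeddingResult:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared distance matrix, ``B = -1/2 J D^2 J``, and
    takes coordinates from the top ``dims`` eigenpairs with positive
    eigenvalues.  Dimensions whose eigenvalues are non-positive come out as
    zero coordinates; the full eigenvalue spectrum is reported so negative
    eigenvalues (non-Euclidean distances) can be inspected.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = np.zeros((n, dims))
    for axis in range(min(dims, n)):
        if eigval[axis] > 0:
            coords[:, axis] = eigvec[:, axis] * np.sqrt(eigval[axis])
    coords -= coords.mean(axis=0)  # numerically exact centering
    return EmbeddingResult(coordinates=coords, eigenvalues=eigval, ids=ids)
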