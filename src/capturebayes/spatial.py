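"""Spatial machinery: disc correlation kernel, site covariances, 500 m blocking.

The site random effects are correlated through a two-dimensional disc
(circular) kernel: the correlation between two sites equals the normalized
overlap area of two equal discs whose overlap vanishes at the kernel range.
This declines nearly linearly to zero at the range (500 m by default, the
scale of an antechinus home range) and is a valid positive-definite
correlation function in the plane.  The same 500 m scale drives the
single-linkage clustering used to build spatially blocked cross-validation
folds, so that no pair of nearby sites is split between training and test
data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform


class AllocationError(ValueError):
    """Fold allocation is infeasible (fewer spatial clusters than folds)."""


@dataclass(frozen=True)
class DiscKernel:
    """Disc-overlap correlation with zero correlation beyond ``range_m``."""

    range_m: float = 500.0

    def __post_init__(self):
        if not self.range_m > 0:
            raise ValueError(f"range_m must be > 0, got {self.range_m}")

    def __call__(self, distance) -> np.ndarray:
        return disc_correlation(distance, self.range_m)


def disc_correlation(distance, range_m: float = 500.0):
    """Correlation of the 2-D disc kernel at the given separation.

    With ``h = distance / range_m``::

        rho(h) = (2/pi) * (arccos(h) - h * sqrt(1 - h^2))   for h < 1
        rho(h) = 0                                          for h >= 1

    the normalized overlap area of two equal discs whose overlap vanishes
    at ``range_m``.  Accepts scalars or arrays; distances must be >= 0.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    h = np.minimum(d / range_m, 1.0)
    rho = (2.0 / np.pi) * (np.arccos(h) - h * np.sqrt(np.maximum(1.0 - h * h, 0.0)))
    # exact endpoints
    rho = np.where(h >= 1.0, 0.0, rho)
    if np.isscalar(distance):
        return float(rho)
    return rho


@dataclass
class SiteCovariance:
    """Covariance matrix of the site random effects under the disc kernel."""

    matrix: np.ndarray
    sigma_site: float
    kernel: DiscKernel
    jitter: float

    @property
    def correlation(self) -> np.ndarray:
        """Unit-variance correlation matrix (jittered diagonal)."""
        if self.sigma_site > 0:
            return self.matrix / self.sigma_site**2
        return np.eye(len(self.matrix)) * (1.0 + self.jitter)

    def cholesky(self) -> np.ndarray:
        return np.linalg.cholesky(self.correlation)


def build_site_covariance(coords: np.ndarray, sigma_site: float,
                          kernel: DiscKernel = DiscKernel()) -> SiteCovariance:
    """Covariance ``sigma_site^2 * rho(d_ij)`` over unique site coordinates.

    A relative jitter of 1e-8 is added to the diagonal for factorization
    stability.  Duplicate coordinates for distinct sites are allowed
    (perfect correlation) but trigger a warning.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if sigma_site < 0:
        raise ValueError("sigma_site must be >= 0")
    m = len(coords)
    if m > 1:
        d = squareform(pdist(coords))
        if np.any(d[np.triu_indices(m, k=1)] == 0.0):
            warnings.warn("duplicate coordinates: perfectly correlated sites",
                          stacklevel=2)
    else:
        d = np.zeros((1, 1))
    jitter = 1e-8
    cov = sigma_site**2 * disc_correlation(d, kernel.range_m)
    cov[np.diag_indices(m)] = sigma_site**2 * (1.0 + jitter)
    return SiteCovariance(matrix=cov, sigma_site=float(sigma_site),
                          kernel=kernel, jitter=jitter)


def cluster_sites(coords: np.ndarray, linkage_m: float = 500.0) -> np.ndarray:
    """Single-linkage clusters: connected components of the <= linkage graph.

    Two sites share a label iff they are connected by a chain of pairwise
    distances <= ``linkage_m``.
    """
    if not linkage_m > 0:
        raise ValueError("linkage_m must be > 0")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    m = len(coords)
    if m == 1:
        return np.zeros(1, dtype=int)
    adj = squareform(pdist(coords)) <= linkage_m
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def allocate_folds(clusters: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deal spatial clusters round-robin into ``k`` folds.

    Clusters (not sites) are shuffled by ``seed`` and assigned cyclically,
    so every site of a cluster shares a fold and fold sizes in clusters
    differ by at most one.  Returns a per-site fold id.
    """
    clusters = np.asarray(clusters)
    ids = np.unique(clusters)
    if len(ids) < k:
        raise AllocationError(
            f"{len(ids)} spatial clusters cannot fill {k} folds; use a smaller k"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(ids)
    fold_of_cluster = {int(c): i % k for i, c in enumerate(order)}
    return np.array([fold_of_cluster[int(c)] for c in clusters])
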