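"""Gaussian mixture likelihood machinery for bead models.

Atoms (or weighted voxels) are modeled as draws from K equal-weight
spherical Gaussians centered on the beads. All likelihoods are computed in
log space with max-subtraction; weighted input generalizes every formula so
atomic (unit weight) and density-map clouds share the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

__all__ = [
    "AssignmentMap",
    "ClusterSummary",
    "log_gaussian3",
    "marginal_log_likelihood",
    "augmented_log_likelihood",
    "summarize",
    "chi_square",
]


@dataclass
class AssignmentMap:
    """Hard atom-to-bead mapping: for each point, the index of its bead."""

    bead_index: np.ndarray
    n_beads: int

    def __post_init__(self):
        self.bead_index = np.asarray(self.bead_index, dtype=np.intp)
        if self.bead_index.ndim != 1:
            raise ValueError("bead_index must be a 1D integer vector")
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")
        if self.bead_index.size and (
            self.bead_index.min() < 0 or self.bead_index.max() >= self.n_beads
        ):
            raise ValueError("bead indices must lie in [0, n_beads)")

    def __len__(self) -> int:
        return len(self.bead_index)


@dataclass
class ClusterSummary:
    """Per-bead summary statistics of an assignment.

    ``counts`` are weighted point counts, ``centers`` the weighted centroids
    of the assigned points and ``spreads_sq`` their mean squared deviation
    (Å²). Empty clusters have count 0 and NaN centers — flagged, never
    fabricated.
    """

    counts: np.ndarray
    centers: np.ndarray
    spreads_sq: np.ndarray

    @property
    def occupied(self) -> np.ndarray:
        """Boolean mask of clusters with at least one assigned point."""
        return self.counts > 0


def log_gaussian3(x, mu, s: float) -> float:
    """Log-density of an isotropic 3D Gaussian with standard deviation s."""
    if s <= 0:
        raise ValueError("s must be positive")
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    r2 = np.sum((x - mu) ** 2, axis=-1)
    return -1.5 * np.log(2.0 * np.pi * s * s) - r2 / (2.0 * s * s)


def _log_component_matrix(cloud, X, s):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("bead positions must be finite")
    d2 = cdist(cloud.positions, X, "sqeuclidean")
    return -1.5 * np.log(2.0 * np.pi * s * s) - d2 / (2.0 * s * s)


def marginal_log_likelihood(cloud, X, s: float) -> float:
    """Weighted log-likelihood of the cloud under the K-component mixture.

    Computes ``sum_n w_n log[(1/K) sum_k N(x_n; X_k, s^2)]`` with
    log-sum-exp stabilization. For unit weights this is the exact mixture
    log-likelihood of the atomic structure.
    """
    if s <= 0:
        raise ValueError("s must be positive")
    log_comp = _log_component_matrix(cloud, X, s)
    K = log_comp.shape[1]
    per_point = logsumexp(log_comp, axis=1) - np.log(K)
    return float(cloud.weights @ per_point)


def augmented_log_likelihood(cloud, X, assignment: AssignmentMap, s: float) -> float:
    """Log-likelihood given a hard assignment of every point to a bead.

    Uses the summary-statistics decomposition
    ``-(3 W / 2) ln(2 pi s^2) - (1/2 s^2) sum_k N_k [||X_k - mu_k||^2 + s_k^2]``
    with W the total weight; identical to summing per-point Gaussian
    log-densities at the assigned beads.
    """
    if s <= 0:
        raise ValueError("s must be positive")
    if len(assignment) != len(cloud):
        raise ValueError("assignment length does not match cloud size")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    summary = summarize(cloud, assignment)
    occ = summary.occupied
    resid = np.sum(
        summary.counts[occ]
        * (
            np.sum((X[occ] - summary.centers[occ]) ** 2, axis=1)
            + summary.spreads_sq[occ]
        )
    )
    W = cloud.total_weight
    return float(-1.5 * W * np.log(2.0 * np.pi * s * s) - resid / (2.0 * s * s))


def summarize(cloud, assignment: AssignmentMap) -> ClusterSummary:
    """Weighted per-cluster counts, centers and spreads for an assignment."""
    if len(assignment) != len(cloud):
        raise ValueError("assignment length does not match cloud size")
    K = assignment.n_beads
    z = assignment.bead_index
    w = cloud.weights
    counts = np.bincount(z, weights=w, minlength=K)
    centers = np.full((K, 3), np.nan)
    spreads_sq = np.zeros(K)
    occ = counts > 0
    wx = np.empty((K, 3))
    for axis in range(3):
        wx[:, axis] = np.bincount(z, weights=w * cloud.positions[:, axis], minlength=K)
    centers[occ] = wx[occ] / counts[occ, None]
    r2 = np.sum((cloud.positions - np.where(occ[z, None], centers[z], 0.0)) ** 2, axis=1)
    ssq = np.bincount(z, weights=w * r2, minlength=K)
    spreads_sq[occ] = ssq[occ] / counts[occ]
    return ClusterSummary(counts, centers, spreads_sq)


def chi_square(cloud, X, assignment: AssignmentMap) -> float:
    """Goodness of fit: weighted sum of squared point-to-assigned-bead distances."""
    if len(assignment) != len(cloud):
        raise ValueError("assignment length does not match cloud size")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    diff = cloud.positions - X[assignment.bead_index]
    return float(cloud.weights @ np.sum(diff**2, axis=1))
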