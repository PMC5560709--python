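"""Pairwise coarse-grained potential: features, gradients, Laplacians.

The bead-bead energy is a linear expansion ``E(X) = sum_l lambda_l f_l(X)``
over pair-distance power sums ``f_l = sum_{k<k'} r^(p_l)`` with negative
even exponents; the default pair (-6, -12) realizes a Lennard-Jones form.
Energies are unitless (k_B T = 1 throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import SingularityError

__all__ = [
    "PotentialSpec",
    "LJParameters",
    "features",
    "energy",
    "feature_gradients",
    "feature_laplacians",
    "pair_energy",
    "lambda_to_lj",
    "lj_to_lambda",
]


@dataclass
class PotentialSpec:
    """Defines the feature basis and current coefficients of the potential."""

    exponents: tuple = (-6, -12)
    lambdas: np.ndarray = None
    pair_cutoff: float | None = None

    def __post_init__(self):
        self.exponents = tuple(int(p) for p in self.exponents)
        if len(self.exponents) < 1:
            raise ValueError("need at least one feature exponent")
        if any(p >= 0 or p % 2 != 0 for p in self.exponents):
            raise ValueError("exponents must be strictly negative even integers")
        if self.lambdas is None:
            self.lambdas = np.zeros(len(self.exponents))
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.lambdas.shape != (len(self.exponents),):
            raise ValueError("lambdas must match the number of exponents")

    @property
    def n_features(self) -> int:
        return len(self.exponents)

    def is_lj(self) -> bool:
        return self.exponents == (-6, -12)


@dataclass
class LJParameters:
    """Standard Lennard-Jones constants derived from (lambda_1, lambda_2).

    ``r_cg`` is the bead van der Waals radius: half the pair distance at the
    potential minimum, ``2^(1/6) sigma / 2``. All fields are NaN when the
    coefficients admit no minimum (``defined`` is False); the sampler may
    transiently visit such values.
    """

    sigma: float
    epsilon: float
    r_cg: float = field(default=np.nan)

    def __post_init__(self):
        if np.isnan(self.r_cg) and np.isfinite(self.sigma):
            self.r_cg = 2.0 ** (1.0 / 6.0) * self.sigma / 2.0

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.sigma) and np.isfinite(self.epsilon))

    @classmethod
    def undefined(cls) -> "LJParameters":
        return cls(np.nan, np.nan, np.nan)


def _pair_distances(X, spec: PotentialSpec):
    """Condensed pair distances, with optional cutoff mask applied."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 2:
        raise ValueError("X must have shape (K, 3) with K >= 2")
    r = pdist(X)
    if np.any(r == 0.0):
        raise SingularityError("coincident beads: pair distance of zero")
    if spec.pair_cutoff is not None:
        r = np.where(r <= spec.pair_cutoff, r, np.inf)
    return r


def features(X, spec: PotentialSpec | None = None) -> np.ndarray:
    """Pair-distance power sums ``f_l = sum_{k<k'} r^(p_l)``, one per exponent."""
    spec = spec or PotentialSpec()
    r = _pair_distances(X, spec)
    return np.array([np.sum(r**p) for p in spec.exponents])


def energy(X, spec: PotentialSpec) -> float:
    """Total potential energy ``<lambda, f(X)>``."""
    if not np.any(spec.lambdas):
        # guard r = 0 even for a zero potential
        _pair_distances(X, spec)
        return 0.0
    return float(spec.lambdas @ features(X, spec))


def feature_gradients(X, spec: PotentialSpec | None = None) -> np.ndarray:
    """Analytic gradients of each feature, shape (L, K, 3).

    Pair (k, k') at distance r contributes ``p r^(p-2) (X_k - X_k')`` to the
    gradient at bead k (and the negative at bead k').
    """
    spec = spec or PotentialSpec()
    X = np.asarray(X, dtype=float)
    r = squareform(_pair_distances(X, spec))
    np.fill_diagonal(r, np.inf)
    grads = np.empty((spec.n_features, X.shape[0], 3))
    for l, p in enumerate(spec.exponents):
        coeff = p * r ** (p - 2)  # (K, K), zero beyond cutoff (inf**neg -> 0)
        row = coeff.sum(axis=1)
        grads[l] = X * row[:, None] - coeff @ X
    return grads


def feature_laplacians(X, spec: PotentialSpec | None = None) -> np.ndarray:
    """Laplacian of each feature over all 3K coordinates.

    For a pair at distance r with exponent p the 3D Laplacian of r^p with
    respect to one endpoint is ``p (p + 1) r^(p-2)``; both endpoints
    contribute, giving ``2 p (p + 1) r^(p-2)`` per pair.
    """
    spec = spec or PotentialSpec()
    r = _pair_distances(X, spec)
    return np.array(
        [2.0 * p * (p + 1) * np.sum(r ** (p - 2)) for p in spec.exponents]
    )


def pair_energy(r, lambdas, exponents=(-6, -12)) -> np.ndarray:
    """Energy of a single pair at distance(s) r under the expansion."""
    r = np.asarray(r, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    return sum(lam * r**p for lam, p in zip(lambdas, exponents))


def lambda_to_lj(lambdas) -> LJParameters:
    """Map (lambda_1, lambda_2) for the (-6, -12) basis to (sigma, epsilon, R_CG).

    Solves ``lambda_1 r^-6 + lambda_2 r^-12 = 4 eps [(sigma/r)^12 - (sigma/r)^6]``:
    ``sigma = (-lambda_2 / lambda_1)^(1/6)``, ``eps = lambda_1^2 / (4 lambda_2)``.
    Returns the undefined marker unless ``lambda_1 < 0 < lambda_2`` (no pair
    minimum exists otherwise).
    """
    lam1, lam2 = np.asarray(lambdas, dtype=float)
    if not (lam1 < 0.0 < lam2):
        return LJParameters.undefined()
    sigma = (-lam2 / lam1) ** (1.0 / 6.0)
    epsilon = lam1 * lam1 / (4.0 * lam2)
    return LJParameters(sigma, epsilon)


def lj_to_lambda(params: LJParameters) -> np.ndarray:
    """Inverse mapping: ``lambda_1 = -4 eps sigma^6``, ``lambda_2 = 4 eps sigma^12``."""
    if not (params.sigma > 0 and params.epsilon > 0):
        raise ValueError("sigma and epsilon must be positive")
    s6 = params.sigma**6
    return np.array([-4.0 * params.epsilon * s6, 4.0 * params.epsilon * s6 * s6])
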