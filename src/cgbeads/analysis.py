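"""Post-inference analyses of bead models.

Radial distribution function and Boltzmann-inversion PMF, radius of
gyration, log-log power-law fits, traveling-salesman bead reordering,
model-to-map rendering and cross-correlation, anisotropic-network normal
modes, mode/displacement overlap and thin-plate-spline interpolation of
displacement fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, cKDTree
from scipy.spatial.distance import cdist, pdist, squareform

from .exceptions import ConditioningError, ConnectivityError, UndefinedCorrelationError
from .structure_io import DensityMap

__all__ = [
    "RDFResult",
    "ModeSet",
    "radius_of_gyration",
    "rdf",
    "pmf_from_rdf",
    "fit_power_law",
    "reorder_beads",
    "path_length",
    "render_model_to_map",
    "cross_correlation",
    "max_cross_correlation",
    "anm_modes",
    "mode_overlap",
    "superpose",
    "tps_interpolate",
]


@dataclass
class RDFResult:
    """Radial distribution function estimated from one or more frames."""

    bin_centers: np.ndarray
    g: np.ndarray
    bin_width: float
    n_frames: int

    @property
    def first_peak(self) -> float:
        """Location (bin center, Å) of the global maximum of g."""
        return float(self.bin_centers[np.argmax(self.g)])


@dataclass
class ModeSet:
    """Normal modes of an elastic network, sorted by ascending eigenvalue."""

    eigenvalues: np.ndarray
    modes: np.ndarray  # (3 n_sites, n_modes), columns orthonormal
    n_zero_modes: int

    @property
    def n_sites(self) -> int:
        return self.modes.shape[0] // 3

    def mode(self, number: int) -> np.ndarray:
        """1-based mode as (n_sites, 3) displacements; mode 7 = first internal."""
        return self.modes[:, number - 1].reshape(-1, 3)


def radius_of_gyration(points, weights=None) -> float:
    """Weighted radius of gyration about the weighted centroid, in Å."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if weights is None:
        weights = np.ones(len(points))
    weights = np.asarray(weights, dtype=float)
    center = weights @ points / weights.sum()
    r2 = np.sum((points - center) ** 2, axis=1)
    return float(np.sqrt(weights @ r2 / weights.sum()))


def rdf(frames, bin_width: float = 0.25, r_max: float | None = None) -> RDFResult:
    """Radial distribution function of pooled pair distances.

    ``frames`` is a (K, 3) configuration or an (F, K, 3) stack. Bins are
    normalized by the ideal-gas expectation ``n_pairs 4 pi r^2 dr / V`` with
    V the convex-hull volume of the pooled points — the natural reference
    for a finite, non-periodic system; g then plateaus near 1 in the bulk.
    Bins beyond the system extent tend to 0 by construction.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n_frames, K = frames.shape[:2]
    if K < 2:
        raise ValueError("need at least 2 beads")
    dists = np.concatenate([pdist(f) for f in frames])
    if r_max is None:
        r_max = float(dists.max()) * 1.02
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist, edges = np.histogram(dists, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    try:
        volume = ConvexHull(frames.reshape(-1, 3)).volume
    except Exception:
        # degenerate geometry (collinear/coplanar points): fall back to the
        # bounding-box volume; only the peak locations are meaningful then
        extent = np.ptp(frames.reshape(-1, 3), axis=0)
        volume = float(np.prod(np.maximum(extent, bin_width)))
    n_pairs = n_frames * K * (K - 1) / 2.0
    shell = 4.0 * np.pi * centers**2 * bin_width
    expected = n_pairs * shell / volume
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, hist / expected, 0.0)
    return RDFResult(centers, g, bin_width, n_frames)


def pmf_from_rdf(result: RDFResult) -> np.ndarray:
    """Potential of mean force ``w(r) = -ln g(r)`` (k_B T = 1).

    Bins with g = 0 map to +inf.
    """
    with np.errstate(divide="ignore"):
        return np.where(result.g > 0, -np.log(np.where(result.g > 0, result.g, 1.0)), np.inf)


def fit_power_law(x_values, y_values):
    """Fit ``y = a x^b`` by ordinary least squares of ln y on ln x.

    Returns ``(a, b, residuals)`` with per-point log residuals.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise ValueError("need at least two (x, y) pairs")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive values")
    lx, ly = np.log(x), np.log(y)
    design = np.column_stack([np.ones_like(lx), lx])
    coef, *_ = np.linalg.lstsq(design, ly, rcond=None)
    residuals = ly - design @ coef
    return float(np.exp(coef[0])), float(coef[1]), residuals


def path_length(X, order) -> float:
    """Total Euclidean length of the open path visiting X in the given order."""
    X = np.asarray(X, dtype=float)
    order = np.asarray(order)
    return float(np.sum(np.linalg.norm(np.diff(X[order], axis=0), axis=1)))


def reorder_beads(X, seed: int | None = None) -> np.ndarray:
    """Short open path through all beads (nearest neighbor + 2-opt).

    Renumbering beads so that spatially close beads get similar indices;
    construction starts from the bead farthest from the centroid (an
    extreme point), is refined by 2-opt until no improving segment reversal
    remains, and never exceeds the nearest-neighbor path length.
    """
    X = np.asarray(X, dtype=float)
    K = len(X)
    if K < 2:
        raise ValueError("need at least 2 beads")
    dist = squareform(pdist(X))
    # deterministic multi-start from extreme beads; small instances try all
    extremity = np.argsort(-np.linalg.norm(X - X.mean(axis=0), axis=1))
    starts = extremity if K <= 10 else extremity[:4]
    best_order, best_length = None, np.inf
    for start in starts:
        order = _refine_path(X, dist, _nearest_neighbor_path(dist, int(start)))
        length = path_length(X, order)
        if length < best_length:
            best_order, best_length = order, length
    return best_order


def _nearest_neighbor_path(dist, start: int) -> np.ndarray:
    K = len(dist)
    order = [start]
    remaining = set(range(K)) - {start}
    while remaining:
        last = order[-1]
        nxt = min(remaining, key=lambda j: dist[last, j])
        order.append(nxt)
        remaining.remove(nxt)
    return np.array(order)


def _refine_path(X, dist, order: np.ndarray) -> np.ndarray:
    K = len(order)
    improved = True
    while improved:
        improved = False
        # 2-opt: reverse a segment when it shortens the open path
        for i in range(K - 1):
            before = dist[order[i - 1], order[i]] if i > 0 else 0.0
            for j in range(i + 1, K):
                after = dist[order[j], order[j + 1]] if j < K - 1 else 0.0
                new_before = dist[order[i - 1], order[j]] if i > 0 else 0.0
                new_after = dist[order[i], order[j + 1]] if j < K - 1 else 0.0
                if new_before + new_after < before + after - 1e-12:
                    order[i : j + 1] = order[i : j + 1][::-1]
                    improved = True
                    before = dist[order[i - 1], order[i]] if i > 0 else 0.0
        # or-opt: relocate one bead; escapes 2-opt local optima
        for i in range(K):
            city = order[i]
            prev_c = order[i - 1] if i > 0 else None
            next_c = order[i + 1] if i < K - 1 else None
            removal_gain = 0.0
            if prev_c is not None:
                removal_gain += dist[prev_c, city]
            if next_c is not None:
                removal_gain += dist[city, next_c]
            if prev_c is not None and next_c is not None:
                removal_gain -= dist[prev_c, next_c]
            rest = np.delete(order, i)
            moved = False
            for j in range(K):  # insertion slot in `rest` (0..K-1)
                if j == i:  # re-inserting in place is a no-op
                    continue
                a = rest[j - 1] if j > 0 else None
                b = rest[j] if j < K - 1 else None
                cost = 0.0
                if a is not None:
                    cost += dist[a, city]
                if b is not None:
                    cost += dist[city, b]
                if a is not None and b is not None:
                    cost -= dist[a, b]
                if cost < removal_gain - 1e-12:
                    order = np.insert(rest, j, city)
                    improved = True
                    moved = True
                    break
            if moved:
                break
    return order


def render_model_to_map(model, template: DensityMap, kernel_width: float | None = None) -> DensityMap:
    """Render beads as equal-amplitude Gaussian kernels on the template grid.

    ``kernel_width`` defaults to the model's precision s. Beads outside the
    template bounding box trigger a warning but are still rendered.
    """
    positions = np.asarray(getattr(model, "positions", model), dtype=float)
    if kernel_width is None:
        kernel_width = getattr(model, "s", None)
        if kernel_width is None or not np.isfinite(kernel_width):
            raise ValueError("kernel_width required when the model has no s")
    lo = template.voxel_to_world((0, 0, 0))
    hi = template.voxel_to_world(np.array(template.shape) - 1)
    if np.any(positions < np.minimum(lo, hi)) or np.any(positions > np.maximum(lo, hi)):
        import warnings

        warnings.warn("some beads lie outside the template bounding box")
    centers = template.voxel_centers()
    grid = np.zeros(len(centers))
    norm = (2.0 * np.pi * kernel_width**2) ** -1.5
    chunk = max(1, 4_000_000 // max(len(positions), 1))
    inv = 1.0 / (2.0 * kernel_width**2)
    for lo_i in range(0, len(centers), chunk):
        hi_i = min(lo_i + chunk, len(centers))
        d2 = cdist(centers[lo_i:hi_i], positions, "sqeuclidean")
        grid[lo_i:hi_i] = norm * np.exp(-inv * d2).sum(axis=1)
    return DensityMap(
        grid.reshape(template.shape), template.voxel_size.copy(), template.origin.copy()
    )


def cross_correlation(map_a: DensityMap, map_b: DensityMap, threshold_a=None, threshold_b=None) -> float:
    """Pearson correlation of two maps on the same grid.

    With thresholds given, only voxels where either map exceeds its
    threshold enter the correlation; by default all voxels do.
    """
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share the same grid geometry")
    a = map_a.grid.ravel()
    b = map_b.grid.ravel()
    if threshold_a is not None or threshold_b is not None:
        mask = np.zeros(a.shape, dtype=bool)
        if threshold_a is not None:
            mask |= a > threshold_a
        if threshold_b is not None:
            mask |= b > threshold_b
        a, b = a[mask], b[mask]
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedCorrelationError("cross-correlation undefined: zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def max_cross_correlation(model, template: DensityMap, kernel_widths) -> tuple:
    """Best CC over a scan of rendering kernel widths; returns (cc, width)."""
    best = (-np.inf, np.nan)
    for width in kernel_widths:
        rendered = render_model_to_map(model, template, kernel_width=width)
        cc = cross_correlation(rendered, template)
        if cc > best[0]:
            best = (cc, float(width))
    return best


def anm_modes(sites, cutoff: float) -> ModeSet:
    """Anisotropic-network normal modes of a site network.

    Unit spring constants; contacts are site pairs within the cutoff. The
    Hessian's 3x3 off-diagonal super-element for a contact is the negative
    outer product of the unit bond vector; diagonal blocks are minus the
    row sums. A connected network has exactly six near-zero (rigid-body)
    modes, identified by eigenvalue < 1e-8 times the largest.
    """
    sites = np.asarray(sites, dtype=float)
    n = len(sites)
    pairs = cKDTree(sites).query_pairs(cutoff, output_type="ndarray")
    adjacency = np.zeros((n, n), dtype=bool)
    adjacency[pairs[:, 0], pairs[:, 1]] = True
    adjacency |= adjacency.T
    n_comp, labels = connected_components(adjacency, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ConnectivityError(
            f"network disconnected at cutoff {cutoff}: {n_comp} components "
            f"with sizes {sorted(sizes, reverse=True)}"
        )
    hessian = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        bond = sites[j] - sites[i]
        block = -np.outer(bond, bond) / (bond @ bond)
        hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    eigenvalues, modes = eigh(hessian)
    n_zero = int(np.sum(eigenvalues < 1e-8 * eigenvalues.max()))
    return ModeSet(eigenvalues, modes, n_zero)


def mode_animation_frames(sites, mode, amplitude: float, n_frames: int = 20) -> np.ndarray:
    """Structures displaced sinusoidally along a normal mode.

    Returns an (n_frames, n_sites, 3) stack suitable for multi-model PDB
    export and animation.
    """
    sites = np.asarray(sites, dtype=float)
    mode = np.asarray(mode, dtype=float).reshape(sites.shape)
    phases = np.sin(2.0 * np.pi * np.arange(n_frames) / n_frames)
    return sites[None] + amplitude * phases[:, None, None] * mode[None]


def mode_overlap(mode, delta) -> float:
    """Normalized absolute inner product of a mode and a displacement vector."""
    mode = np.asarray(mode, dtype=float).ravel()
    delta = np.asarray(delta, dtype=float).ravel()
    if mode.shape != delta.shape:
        raise ValueError("mode and displacement must have equal dimensions")
    nm, nd = np.linalg.norm(mode), np.linalg.norm(delta)
    if nm == 0 or nd == 0:
        raise ValueError("zero vector has no direction")
    return float(abs(mode @ delta) / (nm * nd))


def superpose(mobile, reference):
    """Least-squares rigid-body fit of ``mobile`` onto ``reference`` (Kabsch).

    Returns the transformed mobile coordinates.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    rot = (U @ np.diag([1.0, 1.0, d]) @ Vt).T
    return (mobile - mc) @ rot.T + rc


def tps_interpolate(control_points, values, query_points) -> np.ndarray:
    """3D thin-plate-spline interpolation of a vector field.

    Kernel ``phi(r) = r`` (the 3D biharmonic spline) plus an affine part,
    fitted per component with exact interpolation (no smoothing); affine
    fields are reproduced exactly.
    """
    control = np.asarray(control_points, dtype=float)
    values = np.asarray(values, dtype=float)
    query = np.atleast_2d(np.asarray(query_points, dtype=float))
    n = len(control)
    if n < 4:
        raise ConditioningError("need at least 4 control points")
    if values.ndim == 1:
        values = values[:, None]
    phi = cdist(control, control)
    P = np.column_stack([np.ones(n), control])
    system = np.zeros((n + 4, n + 4))
    system[:n, :n] = phi
    system[:n, n:] = P
    system[n:, :n] = P.T
    rhs = np.zeros((n + 4, values.shape[1]))
    rhs[:n] = values
    try:
        sol = np.linalg.solve(system, rhs)
    except np.linalg.LinAlgError as err:
        raise ConditioningError(f"degenerate control geometry: {err}") from err
    phi_q = cdist(query, control)
    Pq = np.column_stack([np.ones(len(query)), query])
    return phi_q @ sol[:n] + Pq @ sol[n:]
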