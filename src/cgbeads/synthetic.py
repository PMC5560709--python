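"""Synthetic data generators: Gaussian-blob clouds and low-resolution maps.

These emulate the generative model (points drawn from spherical Gaussian
clusters) and low-resolution density grids so that every part of the
pipeline is testable without downloading structures or maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import AtomicPointCloud, DensityMap

__all__ = ["BlobSpec", "make_blob_cloud", "make_synthetic_map"]


@dataclass
class BlobSpec:
    """Specification of a cloud of well-separated Gaussian blobs."""

    n_blobs: int = 5
    center_spacing: float = 10.0
    blob_sd: float = 1.0
    points_per_blob: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.n_blobs < 1 or self.points_per_blob < 1:
            raise ValueError("n_blobs and points_per_blob must be >= 1")
        if self.center_spacing <= 0 or self.blob_sd <= 0:
            raise ValueError("center_spacing and blob_sd must be positive")


def make_blob_cloud(spec: BlobSpec):
    """Sample a cloud of spherical Gaussian blobs on a jittered grid.

    Returns ``(cloud, true_centers, true_sd)`` for parameter-recovery tests.
    Centers sit on a cubic grid with the requested spacing, jittered by 10%
    of the spacing so no two runs share exact lattice symmetry.
    """
    rng = np.random.default_rng(spec.seed)
    side = int(np.ceil(spec.n_blobs ** (1.0 / 3.0)))
    lattice = np.stack(
        np.meshgrid(*[np.arange(side)] * 3, indexing="ij"), axis=-1
    ).reshape(-1, 3)[: spec.n_blobs]
    centers = lattice * spec.center_spacing + rng.uniform(
        -0.1 * spec.center_spacing, 0.1 * spec.center_spacing, (spec.n_blobs, 3)
    )
    points = centers[:, None, :] + spec.blob_sd * rng.standard_normal(
        (spec.n_blobs, spec.points_per_blob, 3)
    )
    cloud = AtomicPointCloud(points.reshape(-1, 3), source_id="synthetic")
    return cloud, centers, spec.blob_sd


def make_synthetic_map(
    cloud: AtomicPointCloud, voxel_size: float = 2.0, kernel_width: float = 3.0
) -> DensityMap:
    """Render a point cloud as a Gaussian-kernel density on a padded grid.

    The grid covers the cloud's bounding box with 5 kernel widths of
    padding, so the total density approximates the total kernel mass.
    """
    voxel_size = float(voxel_size)
    pad = 5.0 * kernel_width
    lo = cloud.positions.min(axis=0) - pad
    hi = cloud.positions.max(axis=0) + pad
    shape = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int) + 1, 1)
    dmap = DensityMap(np.zeros(shape), np.full(3, voxel_size), lo)
    centers = dmap.voxel_centers()
    norm = (2.0 * np.pi * kernel_width**2) ** -1.5
    inv = 1.0 / (2.0 * kernel_width**2)
    grid = np.zeros(len(centers))
    chunk = max(1, 4_000_000 // max(len(cloud), 1))
    for start in range(0, len(centers), chunk):
        stop = min(start + chunk, len(centers))
        d2 = cdist(centers[start:stop], cloud.positions, "sqeuclidean")
        grid[start:stop] = norm * (np.exp(-inv * d2) @ cloud.weights)
    dmap.grid = grid.reshape(shape)
    return dmap
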