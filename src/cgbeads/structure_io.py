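"""Structure and density-map I/O.

Reads atomic structures (PDB) and density maps (MRC/CCP4) into a common
weighted point-cloud representation, and writes bead models back out as
pseudoatom PDB files.

Conventions
-----------
* All coordinates are in Å, kept in the file's frame (no centering).
* Voxel indices are 0-based; the internal grid is indexed ``grid[i, j, k]``
  with axes 0/1/2 corresponding to world x/y/z. The world coordinate of the
  center of voxel ``(i, j, k)`` is ``origin + (i, j, k) * voxel_size``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .exceptions import EmptyInputError

__all__ = [
    "AtomicPointCloud",
    "DensityMap",
    "read_pdb_heavy_atoms",
    "read_density_map",
    "write_density_map",
    "map_to_weighted_points",
    "write_bead_pdb",
]

#: residue names always excluded as solvent
WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: element symbols excluded by the heavy-atom filter
HYDROGEN_ELEMENTS = frozenset({"H", "D"})


@dataclass
class AtomicPointCloud:
    """N weighted 3D points (atoms or map voxels) to be fitted.

    Parameters
    ----------
    positions : ndarray, shape (N, 3)
        Point coordinates in Å.
    weights : ndarray, shape (N,)
        Positive per-point weights; exactly 1.0 for atomic input.
    source_id : str
        Free-text provenance tag (PDB/EMDB code or ``"synthetic"``).
    """

    positions: np.ndarray
    weights: np.ndarray = None
    source_id: str = "unknown"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if self.positions.shape[0] < 1:
            raise EmptyInputError("point cloud must contain at least one point")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.weights is None:
            self.weights = np.ones(len(self.positions))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.positions),):
            raise ValueError("weights must have shape (N,)")
        if not np.all(self.weights > 0):
            raise ValueError("weights must be strictly positive")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def total_weight(self) -> float:
        """Sum of all point weights (equals N for atomic input)."""
        return float(self.weights.sum())

    def centroid(self) -> np.ndarray:
        """Weighted centroid in Å."""
        return self.weights @ self.positions / self.total_weight


@dataclass
class DensityMap:
    """3D scalar grid with voxel size and world origin.

    ``grid[i, j, k]`` lies at ``origin + (i, j, k) * voxel_size`` with axes
    0/1/2 being world x/y/z.
    """

    grid: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    resolution_annotation: float | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError("grid must be a non-empty 3D array")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        if not np.all(self.voxel_size > 0):
            raise ValueError("voxel_size must be positive on all axes")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """World coordinates (Å) of voxel centers given (…, 3) indices."""
        return self.origin + np.asarray(ijk, dtype=float) * self.voxel_size

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world coordinates (inverse transform)."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.voxel_size

    def voxel_centers(self) -> np.ndarray:
        """All voxel center coordinates, shape (nx*ny*nz, 3), C-order."""
        nx, ny, nz = self.grid.shape
        idx = np.stack(
            np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        return self.voxel_to_world(idx)


def read_pdb_heavy_atoms(path, include_hetero: bool = False) -> AtomicPointCloud:
    """Read the heavy atoms of the first model of a PDB file.

    Hydrogen and deuterium are removed, waters are always excluded, and
    alternate locations are resolved to the highest-occupancy conformer
    (ties broken by file order). HETATM records are kept only when
    ``include_hetero`` is set.

    Raises
    ------
    EmptyInputError
        If no heavy atom survives the filter.
    """
    pdb_file = pdb.PDBFile.read(path)
    atoms = pdb.get_structure(pdb_file, model=1, altloc="occupancy")
    element = np.char.upper(atoms.element)
    mask = ~np.isin(element, list(HYDROGEN_ELEMENTS))
    mask &= ~np.isin(atoms.res_name, list(WATER_RESIDUES))
    if not include_hetero:
        mask &= ~atoms.hetero
    if not mask.any():
        raise EmptyInputError(f"no heavy atoms in {path} after filtering")
    coords = np.asarray(atoms.coord[mask], dtype=float)
    return AtomicPointCloud(coords, np.ones(len(coords)), source_id=str(path))


# ---------------------------------------------------------------------------
# MRC/CCP4: minimal MRC2014 reader/writer (mode 0/1/2/6, axis-order aware).
# ---------------------------------------------------------------------------

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def read_density_map(path) -> DensityMap:
    """Read an MRC/CCP4 map, normalizing header axis permutations.

    The MAPC/MAPR/MAPS fields may permute column/row/section axes; the
    returned grid is always indexed [x, y, z]. The origin is taken from the
    ORIGIN header record if set, otherwise from NXSTART/NYSTART/NZSTART.
    """
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise ValueError(f"{path}: truncated MRC header")
        ints = struct.unpack("<56i", header[:224])
        floats = struct.unpack("<56f", header[:224])
        nc, nr, ns = ints[0:3]
        mode = ints[3]
        ncstart, nrstart, nsstart = ints[4:7]
        mx, my, mz = ints[7:10]
        cella = np.array(floats[10:13])
        mapc, mapr, maps_ = ints[16:19]
        nsymbt = ints[23]
        origin_xyz = np.array(floats[49:52])
        if mode not in _MRC_MODES:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        if sorted([mapc, mapr, maps_]) != [1, 2, 3]:
            raise ValueError(f"{path}: malformed axis mapping {(mapc, mapr, maps_)}")
        if min(nc, nr, ns) < 1 or min(mx, my, mz) < 1:
            raise ValueError(f"{path}: non-positive grid dimensions")
        fh.seek(1024 + max(nsymbt, 0))
        data = np.frombuffer(fh.read(), dtype=_MRC_MODES[mode], count=nc * nr * ns)

    # data is stored sections-rows-columns (slowest to fastest)
    grid_crs = data.reshape(ns, nr, nc).astype(float)
    # crs axis i of grid_crs[::-1] ordering -> world axis; build transpose so
    # result axes are x, y, z
    crs_to_xyz = {0: mapc - 1, 1: mapr - 1, 2: maps_ - 1}  # c/r/s -> world axis
    grid_cfirst = grid_crs.transpose(2, 1, 0)  # now indexed [c, r, s]
    axis_order = [0, 0, 0]
    for crs_axis, world_axis in crs_to_xyz.items():
        axis_order[world_axis] = crs_axis
    grid = np.ascontiguousarray(grid_cfirst.transpose(axis_order))

    dims_xyz = np.empty(3)
    start_xyz = np.empty(3)
    sampling = np.array([mx, my, mz], dtype=float)
    for crs_axis, (n, start) in enumerate(
        zip((nc, nr, ns), (ncstart, nrstart, nsstart))
    ):
        dims_xyz[crs_to_xyz[crs_axis]] = n
        start_xyz[crs_to_xyz[crs_axis]] = start
    voxel_size = cella / sampling
    if np.any(origin_xyz != 0):
        origin = origin_xyz
    else:
        origin = start_xyz * voxel_size
    return DensityMap(grid, voxel_size, origin)


def write_density_map(dmap: DensityMap, path) -> None:
    """Write a map as MRC2014, mode 2 (float32), canonical axis order."""
    grid = np.asarray(dmap.grid, dtype=np.float32)
    nx, ny, nz = grid.shape
    header = np.zeros(256, dtype=np.int32)
    header_f = header.view(np.float32)
    header[0:3] = (nx, ny, nz)
    header[3] = 2
    header[7:10] = (nx, ny, nz)
    header_f[10:13] = np.array(grid.shape) * dmap.voxel_size
    header_f[13:16] = 90.0
    header[16:19] = (1, 2, 3)
    header_f[19] = grid.min()
    header_f[20] = grid.max()
    header_f[21] = grid.mean()
    header[22] = 1  # ISPG: P1
    header_f[49:52] = dmap.origin
    header[52] = int.from_bytes(b"MAP ", "little")
    header[53] = int.from_bytes(bytes([0x44, 0x41, 0, 0]), "little")  # little-endian stamp
    with open(path, "wb") as fh:
        fh.write(header.tobytes())
        fh.write(grid.transpose(2, 1, 0).tobytes())


def map_to_weighted_points(dmap: DensityMap, threshold: float) -> AtomicPointCloud:
    """Convert voxels above ``threshold`` to a weighted point cloud.

    Weights are density minus threshold (insensitive to the map's additive
    baseline), rescaled to mean 1 so the cloud's total weight equals the
    surviving voxel count.

    Raises
    ------
    EmptyInputError
        If no voxel exceeds the threshold.
    """
    mask = dmap.grid > threshold
    if not mask.any():
        raise EmptyInputError("no voxel above threshold")
    idx = np.argwhere(mask)
    weights = dmap.grid[mask] - threshold
    weights = weights * (weights.size / weights.sum())
    positions = dmap.voxel_to_world(idx)
    return AtomicPointCloud(positions, weights, source_id="density-map")


def write_bead_pdb(
    model, path, order: np.ndarray | None = None, remarks: dict | None = None
) -> None:
    """Write bead positions as pseudoatom ATOM records.

    Parameters
    ----------
    model : BeadModel or ndarray
        Bead model (uses its ``positions``) or a (K, 3) coordinate array.
    path : path-like
        Output file.
    order : ndarray, optional
        Permutation of 0..K-1 giving the record order (e.g. from TSP
        reordering); identity when omitted.
    remarks : dict, optional
        Extra key/value pairs recorded as REMARK 3 lines; ``r_cg`` and ``s``
        from the model are included automatically when available.
    """
    positions = np.asarray(getattr(model, "positions", model), dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3 or len(positions) < 1:
        raise ValueError("model must provide (K, 3) bead positions, K >= 1")
    order = np.arange(len(positions)) if order is None else np.asarray(order)
    info = {}
    for key in ("r_cg", "s"):
        value = getattr(model, key, None)
        if value is not None and np.isfinite(value):
            info[key] = value
    if remarks:
        info.update(remarks)

    lines = []
    for key, value in info.items():
        lines.append(f"REMARK   3 {key.upper()} = {value:.6g}")
    lines.extend(_bead_records(positions, order))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _bead_records(positions, order):
    records = []
    for serial, k in enumerate(order, start=1):
        x, y, z = positions[k]
        res_id = serial % 10000  # PDB residue field is 4 characters
        records.append(
            f"ATOM  {serial % 100000:5d}  BB  BEA A{res_id:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    return records


def write_multimodel_pdb(frames, path, order: np.ndarray | None = None) -> None:
    """Write a stack of bead configurations as a multi-model PDB.

    Useful for trace snapshots and for animating normal modes.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise ValueError("frames must have shape (n_models, K, 3)")
    order = np.arange(frames.shape[1]) if order is None else np.asarray(order)
    lines = []
    for i, frame in enumerate(frames, start=1):
        lines.append(f"MODEL     {i:4d}")
        lines.extend(_bead_records(frame, order))
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
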