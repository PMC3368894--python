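"""Global 3D grids around a query protein.

``compute_occupancy`` marks cells inside the protein's van der Waals volume.
``project_pdms`` transfers each surface atom's canonical contact histograms
into the global frame via its local frame, splatting cell masses
trilinearly, averaging over contributing atoms and zeroing occupied cells.
The result is one probability-density map per interacting atom type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .atom_types import N_TYPES
from .kb import KnowledgeBase, local_frames
from .structure import Structure

__all__ = ["GridSpec", "OccupancyGrid", "DensityGrid", "grid_for_structure",
           "compute_occupancy", "project_pdms"]

DEFAULT_SPACING = 1.0
DEFAULT_MARGIN = 6.0


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned cubic-cell grid: origin is the corner of cell (0,0,0)."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def cell_centers(self) -> np.ndarray:
        axes = [np.asarray(self.origin)[k] + (np.arange(self.dims[k]) + 0.5) * self.spacing
                for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def covers(self, xyz: np.ndarray, pad: float = 0.0) -> bool:
        lo = np.asarray(self.origin) + pad
        hi = np.asarray(self.origin) + np.asarray(self.dims) * self.spacing - pad
        return bool(np.all(xyz >= lo) and np.all(xyz <= hi))


def grid_for_structure(structure: Structure, spacing: float = DEFAULT_SPACING,
                       margin: float = DEFAULT_MARGIN) -> GridSpec:
    """Grid covering the structure's bounding box plus a margin."""
    xyz = structure.coords()
    lo = xyz.min(axis=0) - margin
    hi = xyz.max(axis=0) + margin
    dims = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) for k in range(3))
    return GridSpec(origin=tuple(float(v) for v in lo), spacing=spacing, dims=dims)


@dataclass
class OccupancyGrid:
    spec: GridSpec
    occupied: np.ndarray   # bool, shape dims

    def free_fraction(self) -> float:
        return 1.0 - float(self.occupied.mean())


@dataclass
class DensityGrid:
    """Stack of PDM values, one (nx,ny,nz) map per interacting type 1..31."""

    spec: GridSpec
    values: np.ndarray     # (31, nx, ny, nz), >= 0
    n_contributors: int = 0

    def save(self, path) -> None:
        np.savez_compressed(path, values=self.values,
                            origin=np.asarray(self.spec.origin),
                            spacing=self.spec.spacing,
                            dims=np.asarray(self.spec.dims),
                            n_contributors=self.n_contributors)

    @classmethod
    def load(cls, path) -> "DensityGrid":
        with np.load(path) as z:
            spec = GridSpec(origin=tuple(z["origin"]), spacing=float(z["spacing"]),
                            dims=tuple(int(d) for d in z["dims"]))
            return cls(spec=spec, values=z["values"],
                       n_contributors=int(z["n_contributors"]))


def write_dx(grid: DensityGrid, type_id: int, path) -> None:
    """Export one PDM as an OpenDX scalar field for visualization."""
    spec = grid.spec
    nx, ny, nz = spec.dims
    vals = grid.values[type_id - 1].ravel()
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        ox, oy, oz = (spec.origin[k] + 0.5 * spec.spacing for k in range(3))
        fh.write(f"origin {ox:.4f} {oy:.4f} {oz:.4f}\n")
        fh.write(f"delta {spec.spacing:.4f} 0 0\n")
        fh.write(f"delta 0 {spec.spacing:.4f} 0\n")
        fh.write(f"delta 0 0 {spec.spacing:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {vals.size} "
                 "data follows\n")
        for i in range(0, vals.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in vals[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def compute_occupancy(structure: Structure, spec: GridSpec) -> OccupancyGrid:
    """Cell occupied iff its centre lies within some atom's vdW radius."""
    xyz = structure.coords()
    radii = structure.radii()
    if not (spec.covers(xyz.min(axis=0)) and spec.covers(xyz.max(axis=0))):
        raise ValueError("grid does not cover the structure")
    centers = spec.cell_centers()
    tree = cKDTree(centers)
    occ = np.zeros(spec.n_cells, dtype=bool)
    for x, r in zip(xyz, radii):
        occ[tree.query_ball_point(x, r)] = True
    return OccupancyGrid(spec=spec, occupied=occ.reshape(spec.dims))


def _trilinear_splat(flat: np.ndarray, spec: GridSpec,
                     points: np.ndarray, masses: np.ndarray) -> None:
    """Deposit masses (m, C) at points (m, 3) into flat grids (C, n_cells).

    Standard 8-corner trilinear weights on the cell-centre lattice; corners
    falling outside the grid lose their share (callers keep a margin so the
    loss is negligible for in-range contributions).
    """
    nx, ny, nz = spec.dims
    h = spec.spacing
    # continuous index on the cell-centre lattice
    u = (points - np.asarray(spec.origin)) / h - 0.5
    i0 = np.floor(u).astype(int)
    frac = u - i0
    for corner in range(8):
        off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        idx = i0 + off
        w = np.prod(np.where(off == 1, frac, 1.0 - frac), axis=1)
        ok = np.all((idx >= 0) & (idx < np.array([nx, ny, nz])), axis=1)
        if not np.any(ok):
            continue
        flat_idx = (idx[ok, 0] * ny + idx[ok, 1]) * nz + idx[ok, 2]
        wm = masses[ok] * w[ok, None]          # (m_ok, C)
        for c in range(masses.shape[1]):
            flat[c] += np.bincount(flat_idx, weights=wm[:, c], minlength=flat.shape[1])


def project_pdms(query: Structure, kb: KnowledgeBase,
                 spec: GridSpec | None = None,
                 occupancy: OccupancyGrid | None = None,
                 mode: str = "trilinear",
                 average: bool = True) -> DensityGrid:
    """Project the knowledge base around a query protein.

    Every surface protein atom with a local frame adds its normalized
    canonical histograms, rigidly placed by its frame, into the 31 global
    maps.  Maps are divided by the number of contributing atoms (so the
    density level is comparable across proteins) and cells inside the
    protein's vdW volume are zeroed.
    """
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    spec = spec or grid_for_structure(query)
    frames = local_frames(query)
    values = np.zeros((N_TYPES, spec.n_cells))
    # sparse canonical histograms per centre type
    sparse: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for t in kb.counts:
        norm = kb.normalized(t).reshape(N_TYPES, -1)
        nz = np.nonzero(norm.any(axis=0))[0]
        if nz.size:
            sparse[t] = (kb.cell_centers()[nz], norm[:, nz].T)   # (m,3), (m,31)
    n_contrib = 0
    skipped = 0
    for i, a in enumerate(query.atoms):
        if a.type_id is None or not (1 <= a.type_id <= 30) or not a.is_surface:
            continue
        if i not in frames:
            skipped += 1
            continue
        if a.type_id not in sparse:
            n_contrib += 1   # contributes zero density but counts toward averaging
            continue
        local_pts, masses = sparse[a.type_id]
        pts = a.xyz + local_pts @ frames[i].T
        if mode == "trilinear":
            _trilinear_splat(values, spec, pts, masses)
        else:
            idx = np.floor((pts - np.asarray(spec.origin)) / spec.spacing).astype(int)
            ok = np.all((idx >= 0) & (idx < np.array(spec.dims)), axis=1)
            flat_idx = (idx[ok, 0] * spec.dims[1] + idx[ok, 1]) * spec.dims[2] + idx[ok, 2]
            for c in range(N_TYPES):
                values[c] += np.bincount(flat_idx, weights=masses[ok, c],
                                         minlength=spec.n_cells)
        n_contrib += 1
    if skipped:
        warnings.warn(f"{skipped} surface atom(s) without a local frame skipped in projection")
    if average and n_contrib > 0:
        values /= n_contrib
    occupancy = occupancy or compute_occupancy(query, spec)
    values = values.reshape((N_TYPES,) + spec.dims)
    values[:, occupancy.occupied] = 0.0
    return DensityGrid(spec=spec, values=values, n_contributors=n_contrib)
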