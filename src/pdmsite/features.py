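"""The 32 physicochemical-complementarity attributes per surface atom.

For surface atom i: S(i,j) sums PDM values of interacting type j over grid
cells within 5 A; A(i,j) is a distance-tapered weighted average of S(k,j)
over surface atoms k within a 10 A patch; A(i,32) is the unoccupied-space
fraction of the 10 A sphere (local surface geometry, convex surfaces score
high).  Raw attributes are rescaled to [0,1] against dataset-level
normalization constants (medians of per-protein extrema).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from .atom_types import N_TYPES
from .grids import DensityGrid, OccupancyGrid
from .structure import Structure

__all__ = [
    "sum_local_density", "aggregate_patch", "geometry_feature",
    "NormalizationConstants", "fit_normalization", "scale_feature",
    "compute_raw_features", "linear_taper",
]

DENSITY_RADIUS = 5.0
PATCH_RADIUS = 10.0
N_FEATURES = 32


def _sphere_cell_indices(spec, center: np.ndarray, radius: float,
                         require_inside: bool) -> np.ndarray:
    """Flat indices of cells whose centres lie within radius of center.

    With require_inside, raises when the sphere exits the grid; otherwise
    out-of-grid cells are simply absent from the result.
    """
    origin = np.asarray(spec.origin)
    h = spec.spacing
    lo_i = np.floor((center - radius - origin) / h - 0.5).astype(int)
    hi_i = np.ceil((center + radius - origin) / h - 0.5).astype(int)
    if require_inside and (np.any(lo_i < 0) or np.any(hi_i >= np.array(spec.dims))):
        raise ValueError("sphere exits grid; increase the grid margin")
    lo_c = np.maximum(lo_i, 0)
    hi_c = np.minimum(hi_i, np.array(spec.dims) - 1)
    axes = [origin[k] + (np.arange(lo_c[k], hi_c[k] + 1) + 0.5) * h for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = ((pts - center) ** 2).sum(axis=1) <= radius ** 2
    ii, jj, kk = np.meshgrid(*[np.arange(lo_c[k], hi_c[k] + 1) for k in range(3)],
                             indexing="ij")
    flat = (ii.ravel() * spec.dims[1] + jj.ravel()) * spec.dims[2] + kk.ravel()
    return flat[inside]


def sum_local_density(atom_xyz: np.ndarray, grid: DensityGrid,
                      radius: float = DENSITY_RADIUS) -> np.ndarray:
    """S(i, j) for j = 1..31: unweighted sum of PDM values within radius."""
    flat = _sphere_cell_indices(grid.spec, np.asarray(atom_xyz, float), radius,
                                require_inside=True)
    vals = grid.values.reshape(N_TYPES, -1)
    return vals[:, flat].sum(axis=1)


def linear_taper(d: np.ndarray, cutoff: float = PATCH_RADIUS) -> np.ndarray:
    """Default distance weight: 1 - d/cutoff, zero at the patch boundary."""
    return np.maximum(0.0, 1.0 - d / cutoff)


def aggregate_patch(index: int, coords: np.ndarray, s_values: np.ndarray,
                    radius: float = PATCH_RADIUS, weight=linear_taper) -> np.ndarray:
    """A(i, j) for j <= 31: weighted average of S(k, j) over the patch.

    ``coords``/``s_values`` enumerate the predictable surface atoms; the
    patch of atom ``index`` is every such atom within ``radius`` (itself
    included at distance zero).
    """
    d = np.linalg.norm(coords - coords[index], axis=1)
    sel = d <= radius
    w = weight(d[sel], radius)
    tot = w.sum()
    if tot <= 0:
        raise ValueError("no patch neighbours with positive weight")
    return (w[:, None] * s_values[sel]).sum(axis=0) / tot


def geometry_feature(atom_xyz: np.ndarray, occupancy: OccupancyGrid,
                     radius: float = PATCH_RADIUS) -> float:
    """Fraction of the 10 A sphere not occupied by protein vdW volume.

    Counts sphere cells on the occupancy lattice; cells beyond the grid are
    free by construction (the grid margin exceeds every vdW radius), so the
    sphere may extend past the grid without error.
    """
    spec = occupancy.spec
    center = np.asarray(atom_xyz, float)
    flat = _sphere_cell_indices(spec, center, radius, require_inside=False)
    n_occupied = int(occupancy.occupied.ravel()[flat].sum())
    # total sphere cells counted on an unbounded lattice of the same spacing
    h = spec.spacing
    lo = np.floor((center - radius - np.asarray(spec.origin)) / h - 0.5).astype(int)
    hi = np.ceil((center + radius - np.asarray(spec.origin)) / h - 0.5).astype(int)
    axes = [np.asarray(spec.origin)[k] + (np.arange(lo[k], hi[k] + 1) + 0.5) * h
            for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    n_total = int((((pts - center) ** 2).sum(axis=1) <= radius ** 2).sum())
    if n_total == 0:
        raise ValueError("sphere contains no lattice cells")
    return 1.0 - n_occupied / n_total


def compute_raw_features(structure: Structure, grid: DensityGrid,
                         occupancy: OccupancyGrid,
                         predictable: list[int],
                         density_radius: float = DENSITY_RADIUS,
                         patch_radius: float = PATCH_RADIUS,
                         weight=linear_taper) -> np.ndarray:
    """Raw attribute matrix A, shape (n_predictable, 32)."""
    if not predictable:
        return np.zeros((0, N_FEATURES))
    coords = np.array([structure.atoms[i].xyz for i in predictable])
    s = np.array([sum_local_density(x, grid, density_radius) for x in coords])
    out = np.empty((len(predictable), N_FEATURES))
    for r in range(len(predictable)):
        out[r, :N_TYPES] = aggregate_patch(r, coords, s, patch_radius, weight)
        out[r, N_TYPES] = geometry_feature(coords[r], occupancy, patch_radius)
    return out


@dataclass
class NormalizationConstants:
    """Medians of per-protein attribute extrema over a training collection."""

    m_min: np.ndarray    # (32,)
    m_max: np.ndarray    # (32,)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"m_min": self.m_min.tolist(), "m_max": self.m_max.tolist()}, fh)

    @classmethod
    def load(cls, path) -> "NormalizationConstants":
        with open(path) as fh:
            d = json.load(fh)
        return cls(m_min=np.asarray(d["m_min"]), m_max=np.asarray(d["m_max"]))


def fit_normalization(per_protein_features: list[np.ndarray]) -> NormalizationConstants:
    """M_min/M_max per attribute as medians of per-protein minima/maxima."""
    mats = [m for m in per_protein_features if len(m)]
    if not mats:
        raise ValueError("no proteins with predictable atoms")
    mins = np.array([m.min(axis=0) for m in mats])
    maxs = np.array([m.max(axis=0) for m in mats])
    return NormalizationConstants(m_min=np.median(mins, axis=0),
                                  m_max=np.median(maxs, axis=0))


def scale_feature(raw: np.ndarray, constants: NormalizationConstants) -> np.ndarray:
    """Clamp-then-linear rescaling of raw attributes into [0, 1].

    a = 1 above M_max, 0 below M_min, linear in between; a degenerate
    attribute (M_min == M_max) maps to 0.5 at the point.
    """
    raw = np.asarray(raw, dtype=float)
    span = constants.m_max - constants.m_min
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (raw - constants.m_min) / span
    a = np.where(span <= 0, np.where(raw > constants.m_max, 1.0,
                                     np.where(raw < constants.m_min, 0.0, 0.5)), a)
    return np.clip(a, 0.0, 1.0)
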