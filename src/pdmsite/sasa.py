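"""Solvent-accessible surface area by Shrake-Rupley spherical quadrature.

Each atom's accessible sphere (vdW radius + probe) is sampled with a
Fibonacci point set; a point is accessible when it lies outside every
neighbouring atom's probe-expanded sphere.  SASA is the accessible fraction
times the sphere area.  Deterministic for a fixed point count.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure

__all__ = ["fibonacci_sphere", "shrake_rupley", "compute_sasa"]

DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (golden-spiral construction)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(xyz: np.ndarray, radii: np.ndarray,
                  probe_radius: float = DEFAULT_PROBE,
                  n_points: int = DEFAULT_POINTS,
                  point_rotation: np.ndarray | None = None) -> np.ndarray:
    """Per-sphere SASA (A^2) for arbitrary coordinates and radii.

    ``point_rotation`` rotates the quadrature point set; passing the same
    rotation applied to the coordinates reproduces the unrotated areas
    exactly, which is how rigid-motion invariance is defined for a fixed
    quadrature.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    n = len(xyz)
    if n == 0:
        return np.zeros(0)
    pts = fibonacci_sphere(n_points)
    if point_rotation is not None:
        pts = pts @ np.asarray(point_rotation, dtype=float).T
    ext = radii + probe_radius
    tree = cKDTree(xyz)
    max_ext = ext.max()
    out = np.empty(n)
    for i in range(n):
        neigh = [j for j in tree.query_ball_point(xyz[i], ext[i] + max_ext) if j != i]
        sphere = xyz[i] + ext[i] * pts
        if neigh:
            nx = xyz[neigh]
            nr = ext[neigh]
            d2 = ((sphere[:, None, :] - nx[None, :, :]) ** 2).sum(axis=2)
            accessible = np.all(d2 >= (nr ** 2)[None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        out[i] = 4.0 * np.pi * ext[i] ** 2 * frac
    return out


def compute_sasa(structure: Structure, probe_radius: float = DEFAULT_PROBE,
                 n_points: int = DEFAULT_POINTS,
                 point_rotation: np.ndarray | None = None) -> np.ndarray:
    """Compute and store unbound-state SASA for every typed atom.

    Untyped atoms are not allowed: typing supplies the radii.
    """
    untyped = [a.key for a in structure.atoms if a.radius is None]
    if untyped:
        raise ValueError(f"{len(untyped)} untyped atom(s) present "
                         f"(e.g. {untyped[:3]}); run assign_atom_types first")
    areas = shrake_rupley(structure.coords(), structure.radii(),
                          probe_radius=probe_radius, n_points=n_points,
                          point_rotation=point_rotation)
    for a, s in zip(structure.atoms, areas):
        a.sasa_u = float(s)
    return areas
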