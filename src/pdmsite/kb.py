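"""Knowledge base of non-covalent contact statistics.

For every protein atom type t (1..30) a canonical-frame 3D histogram per
interacting partner type j (1..31) records where partners of type j sit
around atoms of type t, pooled over a reference structure set.  Pose
invariance comes from expressing each partner displacement in a local
orthonormal frame anchored on the centre atom and its covalent neighbours.
Normalized histograms are the per-atom probability clouds later projected
around query proteins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .atom_types import N_PROTEIN_TYPES, N_TYPES
from .filters import FilterMatrix, permissive_filter_matrix
from .structure import Structure

__all__ = [
    "ContactRule", "PairObservation", "KnowledgeBase",
    "build_local_frame", "local_frames", "harvest_contacts",
    "accumulate_histograms", "build_knowledge_base",
]


@dataclass(frozen=True)
class ContactRule:
    """Distance contact criterion d <= r_i + r_j + tolerance (A)."""

    tolerance: float = 1.4

    def max_distance(self, r_i: float, r_j: float) -> float:
        return r_i + r_j + self.tolerance


@dataclass(frozen=True)
class PairObservation:
    center_type: int          # 1..30
    partner_type: int         # 1..31
    displacement: tuple[float, float, float]   # centre-atom local frame, A


def build_local_frame(center_xyz: np.ndarray, neighbor_xyz: list[np.ndarray]) -> np.ndarray:
    """Right-handed orthonormal frame (columns e1,e2,e3) from two bonded
    directions.  Raises ValueError on collinear input."""
    if len(neighbor_xyz) < 2:
        raise ValueError("need two reference neighbours for a frame")
    v1 = np.asarray(neighbor_xyz[0], dtype=float) - center_xyz
    v2 = np.asarray(neighbor_xyz[1], dtype=float) - center_xyz
    n1 = np.linalg.norm(v1)
    if n1 < 1e-9:
        raise ValueError("degenerate neighbour at centre position")
    e1 = v1 / n1
    w = np.cross(v1, v2)
    nw = np.linalg.norm(w)
    if nw < 1e-8:
        raise ValueError("collinear neighbours; frame undefined")
    e3 = w / nw
    e2 = np.cross(e3, e1)
    return np.column_stack([e1, e2, e3])


def local_frames(structure: Structure) -> dict[int, np.ndarray]:
    """Local frame per atom index, skipping atoms that cannot anchor one.

    Reference directions are the two first covalently bonded heavy
    neighbours in canonical (chain, residue, atom-name) order; a terminal
    atom with a single neighbour borrows that neighbour's next bonded atom.
    """
    adj = structure.bonds()
    atoms = structure.atoms

    def order_key(i: int):
        a = atoms[i]
        return (a.chain, a.res_seq, a.atom_name)

    frames: dict[int, np.ndarray] = {}
    skipped = 0
    for i, a in enumerate(atoms):
        neigh = sorted(adj[i], key=order_key)
        if not neigh:
            skipped += 1
            continue
        refs: list[np.ndarray] = []
        if len(neigh) >= 2:
            refs = [atoms[neigh[0]].xyz, atoms[neigh[1]].xyz]
        else:
            b = neigh[0]
            second = [k for k in sorted(adj[b], key=order_key) if k != i]
            if not second:
                skipped += 1
                continue
            refs = [atoms[b].xyz, atoms[second[0]].xyz]
        try:
            frames[i] = build_local_frame(a.xyz, refs)
        except ValueError:
            skipped += 1
    if skipped:
        warnings.warn(f"{skipped} atom(s) without a local frame were skipped")
    return frames


def harvest_contacts(reference: list[Structure],
                     filter_matrix: FilterMatrix | None = None,
                     rule: ContactRule = ContactRule(),
                     strict_interior: bool = True) -> list[PairObservation]:
    """Collect filtered non-covalent contact observations.

    Excludes intra-residue pairs, pairs within 3 covalent bonds, pairs
    rejected by the filter matrix, and (in strict-interior mode) pairs where
    either atom has nonzero solvent accessibility.  Each admitted geometric
    pair yields one observation per protein-typed centre (so an (8,8) pair
    in different residues contributes one observation in each direction).
    """
    filter_matrix = filter_matrix or permissive_filter_matrix()
    obs: list[PairObservation] = []
    for st in reference:
        if any(a.type_id is None for a in st.atoms):
            raise ValueError("reference structure has untyped atoms")
        if strict_interior and any(a.sasa_u is None for a in st.atoms):
            raise ValueError("strict-interior harvesting needs SASA; run compute_sasa")
        frames = local_frames(st)
        excluded = st.bonded_within(3)
        xyz = st.coords()
        tree = cKDTree(xyz)
        max_cut = 2 * max(a.radius for a in st.atoms) + rule.tolerance
        for i, j in tree.query_pairs(max_cut):
            a, b = st.atoms[i], st.atoms[j]
            if a.residue_key == b.residue_key:
                continue
            if (min(i, j), max(i, j)) in excluded:
                continue
            d = float(np.linalg.norm(a.xyz - b.xyz))
            if d > rule.max_distance(a.radius, b.radius):
                continue
            if not filter_matrix.admits(a.type_id, b.type_id):
                continue
            if strict_interior and (a.sasa_u > 0.0 or b.sasa_u > 0.0):
                continue
            for ci, pi in ((i, j), (j, i)):
                ca, pa = st.atoms[ci], st.atoms[pi]
                if not (1 <= ca.type_id <= N_PROTEIN_TYPES):
                    continue   # water never a centre
                if ci not in frames:
                    continue
                disp = frames[ci].T @ (pa.xyz - ca.xyz)
                obs.append(PairObservation(ca.type_id, pa.type_id,
                                           tuple(float(x) for x in disp)))
    return obs


@dataclass
class KnowledgeBase:
    """Canonical-frame contact histograms per (centre type, partner type).

    ``counts[t]`` is an array (31, n, n, n) of integer counts over a cubic
    grid spanning [-extent, extent] at the stated spacing; cell (ix,iy,iz)
    covers [-extent + ix*h, -extent + (ix+1)*h) per axis.
    """

    spacing: float
    extent: float
    counts: dict[int, np.ndarray] = field(default_factory=dict)
    dropped: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return int(round(2 * self.extent / self.spacing))

    def total_count(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def cell_centers(self) -> np.ndarray:
        """(n^3, 3) canonical-frame cell centre coordinates."""
        n = self.n_cells
        ax = -self.extent + (np.arange(n) + 0.5) * self.spacing
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def normalized(self, center_type: int) -> np.ndarray:
        """Per-partner-type probability histograms (sum 1 where populated)."""
        c = self.counts[center_type].astype(float)
        totals = c.reshape(N_TYPES, -1).sum(axis=1)
        out = np.zeros_like(c)
        for j in range(N_TYPES):
            if totals[j] > 0:
                out[j] = c[j] / totals[j]
        return out

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"t{t}": c for t, c in self.counts.items()}
        meta = dict(self.metadata)
        meta.update(spacing=self.spacing, extent=self.extent, dropped=self.dropped)
        np.savez_compressed(path, _meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "KnowledgeBase":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["_meta"]))
            counts = {int(k[1:]): z[k] for k in z.files if k.startswith("t")}
        kb = cls(spacing=meta.pop("spacing"), extent=meta.pop("extent"),
                 counts=counts, dropped=meta.pop("dropped", 0))
        kb.metadata = meta
        return kb


def accumulate_histograms(observations: list[PairObservation],
                          spacing: float = 1.0,
                          extent: float = 8.0,
                          metadata: dict | None = None) -> KnowledgeBase:
    """Bin observations into the canonical cubic histograms.

    Displacements outside [-extent, extent) are dropped and counted.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    kb = KnowledgeBase(spacing=spacing, extent=extent, metadata=metadata or {})
    n = kb.n_cells
    for o in observations:
        # boundary guard: a displacement sitting exactly on a cell edge joins
        # the upper cell even under ~1e-13 rigid-motion rounding noise
        idx = np.floor((np.asarray(o.displacement) + extent) / spacing + 1e-9).astype(int)
        if np.any(idx < 0) or np.any(idx >= n):
            kb.dropped += 1
            continue
        if o.center_type not in kb.counts:
            kb.counts[o.center_type] = np.zeros((N_TYPES, n, n, n), dtype=np.int64)
        kb.counts[o.center_type][o.partner_type - 1, idx[0], idx[1], idx[2]] += 1
    return kb


def build_knowledge_base(reference: list[Structure],
                         filter_matrix: FilterMatrix | None = None,
                         rule: ContactRule = ContactRule(),
                         spacing: float = 1.0, extent: float = 8.0,
                         strict_interior: bool = True) -> KnowledgeBase:
    """Harvest + accumulate in one call, recording the rule in metadata."""
    obs = harvest_contacts(reference, filter_matrix, rule, strict_interior)
    meta = {
        "contact_rule": {"kind": "distance", "tolerance": rule.tolerance},
        "strict_interior": strict_interior,
        "n_reference_structures": len(reference),
        "n_observations": len(obs),
    }
    return accumulate_histograms(obs, spacing=spacing, extent=extent, metadata=meta)
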