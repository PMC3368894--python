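"""Structure container, PDB I/O, typing, covalent topology and atom selection.

A :class:`Structure` is an ordered list of heavy-atom sites with enough
annotation (type ID, radius, SASA in unbound/complexed state, fractional
buried area dSASA) to drive the interface-prediction pipeline.  Parsing is
delegated to gemmi; alternate locations keep the highest-occupancy conformer
and hydrogens are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .atom_types import AtomTypeTable, default_atom_type_table

__all__ = [
    "AtomSite", "Structure", "parse_structure", "assign_atom_types",
    "label_ppi_atoms", "select_prediction_atoms", "structure_to_pdb",
    "write_atom_table",
]

#: maximum heavy-atom covalent bond length (A); S-S handled separately
BOND_CUTOFF = 2.0
DISULFIDE_CUTOFF = 2.3
#: peptide C-N distance beyond which the chain is considered broken
CHAIN_BREAK_CUTOFF = 2.5


@dataclass
class AtomSite:
    """One heavy atom with coordinates and pipeline annotations."""

    chain: str
    res_name: str
    res_seq: int
    atom_name: str
    xyz: np.ndarray                    # (3,) Angstrom
    type_id: int | None = None         # 1..31, None if untyped
    radius: float | None = None        # vdW radius, Angstrom
    sasa_u: float | None = None        # unbound-state SASA, A^2
    sasa_c: float | None = None        # complexed-state SASA, A^2
    dsasa: float | None = None         # fractional buried area, [0, 1]
    is_predictable: bool = False

    @property
    def is_surface(self) -> bool:
        return self.sasa_u is not None and self.sasa_u > 0.0

    @property
    def is_ppi(self) -> bool:
        """PPI-site atom: any solvent-accessible area lost on binding."""
        return self.dsasa is not None and self.dsasa > 0.0

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.res_seq, self.atom_name)

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain, self.res_seq)


class Structure:
    """Ordered heavy-atom list with lazily built covalent topology."""

    def __init__(self, atoms: list[AtomSite], provenance: str = ""):
        keys = [a.key for a in atoms]
        if len(set(keys)) != len(keys):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise ValueError(f"duplicate atom keys: {sorted(dupes)[:5]}")
        self.atoms = atoms
        self.provenance = provenance
        self._bonds: list[set[int]] | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(len(self.atoms), 3)

    def radii(self) -> np.ndarray:
        r = [a.radius for a in self.atoms]
        if any(v is None for v in r):
            raise ValueError("untyped atoms present; run assign_atom_types first")
        return np.asarray(r, dtype=float)

    def subset(self, indices) -> "Structure":
        return Structure([self.atoms[i] for i in indices], provenance=self.provenance)

    # -- covalent topology --------------------------------------------------

    def bonds(self) -> list[set[int]]:
        """Adjacency lists inferred from heavy-atom distances.

        Pairs closer than 2.0 A (2.3 A for S-S) and in the same chain, or a
        peptide C-N link, are bonded.  Waters are never bonded.
        """
        if self._bonds is None:
            n = len(self.atoms)
            adj: list[set[int]] = [set() for _ in range(n)]
            if n:
                xyz = self.coords()
                tree = cKDTree(xyz)
                for i, j in tree.query_pairs(DISULFIDE_CUTOFF):
                    a, b = self.atoms[i], self.atoms[j]
                    if a.res_name in ("HOH", "WAT") or b.res_name in ("HOH", "WAT"):
                        continue
                    if a.chain != b.chain:
                        continue
                    d = float(np.linalg.norm(a.xyz - b.xyz))
                    cut = DISULFIDE_CUTOFF if (a.atom_name.startswith("S") and b.atom_name.startswith("S")) else BOND_CUTOFF
                    if d <= cut:
                        adj[i].add(j)
                        adj[j].add(i)
            self._bonds = adj
        return self._bonds

    def bonded_within(self, max_bonds: int = 3) -> set[tuple[int, int]]:
        """Atom index pairs separated by <= max_bonds covalent bonds."""
        adj = self.bonds()
        out: set[tuple[int, int]] = set()
        for start in range(len(self.atoms)):
            frontier = {start}
            seen = {start}
            for _ in range(max_bonds):
                frontier = {k for f in frontier for k in adj[f]} - seen
                seen |= frontier
                for j in frontier:
                    if j > start:
                        out.add((start, j))
        return out

    # -- residue-level helpers ---------------------------------------------

    def residues(self) -> dict[tuple[str, int], list[int]]:
        """Residue key -> atom indices, in file order."""
        out: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_key, []).append(i)
        return out

    def phi_psi_defined(self) -> dict[tuple[str, int], bool]:
        """Whether both backbone dihedrals are defined for each residue.

        phi needs the preceding residue's C within peptide-bond distance of
        this residue's N; psi needs the following residue's N likewise.
        Chain termini and breaks (C-N > 2.5 A) leave a dihedral undefined.
        """
        res = self.residues()
        keys = list(res)
        by_name: dict[tuple[str, int], dict[str, np.ndarray]] = {}
        for k, idxs in res.items():
            by_name[k] = {self.atoms[i].atom_name: self.atoms[i].xyz for i in idxs}
        defined: dict[tuple[str, int], bool] = {}
        for pos, k in enumerate(keys):
            names = by_name[k]
            if not {"N", "CA", "C"} <= names.keys():
                defined[k] = False
                continue
            has_phi = has_psi = False
            if pos > 0 and keys[pos - 1][0] == k[0]:
                prev = by_name[keys[pos - 1]]
                if "C" in prev and np.linalg.norm(prev["C"] - names["N"]) <= CHAIN_BREAK_CUTOFF:
                    has_phi = True
            if pos + 1 < len(keys) and keys[pos + 1][0] == k[0]:
                nxt = by_name[keys[pos + 1]]
                if "N" in nxt and np.linalg.norm(names["C"] - nxt["N"]) <= CHAIN_BREAK_CUTOFF:
                    has_psi = True
            defined[k] = has_phi and has_psi
        return defined


def parse_structure(pdb_text: str, chains: set[str] | None = None,
                    include_waters: bool = False) -> Structure:
    """Parse PDB-format text into a Structure of heavy atoms.

    Hydrogens are discarded; alternate locations resolved to the
    highest-occupancy conformer (tie: first in file).  Waters are retained
    as candidate type-31 sites only when requested.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed PDB input: {exc}") from exc
    if len(st) == 0:
        raise ValueError("no models in PDB input")
    model = st[0]
    atoms: list[AtomSite] = []
    # best-occupancy altloc pick per (chain, resseq, atomname)
    best: dict[tuple[str, int, str], tuple[float, int]] = {}
    order = 0
    records: list[AtomSite] = []
    occs: list[float] = []
    for chain in model:
        cid = chain.name
        if chains is not None and cid not in chains:
            continue
        for residue in chain:
            rname = residue.name.strip().upper()
            is_water = rname in ("HOH", "WAT")
            if is_water and not include_waters:
                continue
            for atom in residue:
                if atom.element.is_hydrogen:
                    continue
                site = AtomSite(
                    chain=cid, res_name=rname, res_seq=residue.seqid.num,
                    atom_name=atom.name.strip().upper(),
                    xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float),
                )
                if not np.all(np.isfinite(site.xyz)):
                    raise ValueError(f"non-finite coordinates at {site.key}")
                k = site.key
                occ = float(atom.occ)
                if k in best:
                    if occ > best[k][0]:
                        best[k] = (occ, len(records))
                else:
                    best[k] = (occ, len(records))
                records.append(site)
                occs.append(occ)
                order += 1
    keep = sorted(idx for _occ, idx in best.values())
    atoms = [records[i] for i in keep]
    if chains is not None:
        present = {a.chain for a in atoms}
        missing = chains - present
        if missing:
            raise ValueError(f"no atoms found for requested chain(s): {sorted(missing)}")
    if not atoms:
        warnings.warn("structure contains no heavy atoms after filtering")
    return Structure(atoms)


def assign_atom_types(structure: Structure,
                      table: AtomTypeTable | None = None) -> Structure:
    """Assign Table-derived type IDs and radii in place; returns structure.

    Atoms without a table entry (non-standard residues, OXT, ...) are left
    untyped with a warning and stay out of prediction.
    """
    table = table or default_atom_type_table()
    untyped = []
    for a in structure.atoms:
        hit = table.lookup(a.res_name, a.atom_name)
        if hit is None:
            untyped.append(a.key)
            a.type_id = None
            a.radius = None
        else:
            a.type_id, a.radius = hit
    if untyped:
        warnings.warn(f"{len(untyped)} atom(s) without a type entry left untyped, "
                      f"e.g. {untyped[:3]}")
    return structure


def label_ppi_atoms(unbound: Structure, complexed: Structure) -> Structure:
    """Attach complexed-state SASA and dSASA labels to the unbound structure.

    dSASA = (SASA_u - SASA_c) / SASA_u for surface atoms, clipped to [0, 1];
    an atom is a PPI-site atom iff dSASA > 0.  Requires a one-to-one key
    match for the unbound atoms within the complexed structure.
    """
    cmap = {a.key: a for a in complexed.atoms}
    missing = [a.key for a in unbound.atoms if a.key not in cmap]
    if missing:
        raise ValueError(f"complexed structure lacks {len(missing)} atom(s), "
                         f"e.g. {missing[:5]}")
    for a in unbound.atoms:
        if a.sasa_u is None:
            raise ValueError("unbound SASA missing; run compute_sasa first")
        ca = cmap[a.key]
        if ca.sasa_u is None:
            raise ValueError("complexed SASA missing; run compute_sasa on the complex")
        a.sasa_c = ca.sasa_u
        if a.sasa_u > 0.0:
            a.dsasa = float(np.clip((a.sasa_u - a.sasa_c) / a.sasa_u, 0.0, 1.0))
        else:
            a.dsasa = None
    return unbound


def select_prediction_atoms(structure: Structure) -> list[int]:
    """Indices of atoms eligible for prediction.

    Surface atoms (SASA_u > 0) of protein types 1..30 whose residue has both
    backbone dihedrals defined (excludes termini and chain breaks).
    """
    defined = structure.phi_psi_defined()
    out = []
    for i, a in enumerate(structure.atoms):
        ok = (a.type_id is not None and 1 <= a.type_id <= 30
              and a.is_surface and defined.get(a.residue_key, False))
        a.is_predictable = bool(ok)
        if ok:
            out.append(i)
    return out


def structure_to_pdb(structure: Structure) -> str:
    """Serialize to PDB text (coordinates at standard 3 d.p. precision)."""
    lines = []
    serial = 0
    for a in structure.atoms:
        serial += 1
        rec = "HETATM" if a.res_name in ("HOH", "WAT") else "ATOM  "
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
        elem = a.atom_name[0]
        lines.append(
            f"{rec}{serial:5d} {name:<4s}{'':1s}{a.res_name:<3s} {a.chain:1s}"
            f"{a.res_seq:4d}    {a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {elem:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_atom_table(structure: Structure, path) -> None:
    """Per-atom TSV: identity, type, SASA values, dSASA and flags."""
    import pandas as pd

    rows = []
    for a in structure.atoms:
        rows.append({
            "chain": a.chain, "res_seq": a.res_seq, "res_name": a.res_name,
            "atom_name": a.atom_name, "type_id": a.type_id,
            "sasa_u": a.sasa_u, "sasa_c": a.sasa_c, "dsasa": a.dsasa,
            "is_surface": a.is_surface, "is_predictable": a.is_predictable,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
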