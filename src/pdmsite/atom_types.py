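"""Heavy-atom chemical typing for the 20 standard amino acids plus water.

Protein heavy atoms are grouped into 30 chemical classes by element,
hybridization and residue context (backbone NH, carbonyl C, aliphatic CH2,
aromatic CH, carboxyl O, ...); crystal-water oxygen is class 31.  Each class
carries a van der Waals radius used for SASA, contact detection and grid
occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["AtomTypeTable", "default_atom_type_table", "N_PROTEIN_TYPES", "N_TYPES", "TYPE_NAMES"]

#: protein atom classes (1..30); water oxygen is 31
N_PROTEIN_TYPES = 30
N_TYPES = 31

#: short chemical name per type ID
TYPE_NAMES = {
    1: "NH1", 2: "C", 3: "CH1E", 4: "O", 5: "CH0", 6: "CH1S", 7: "CH2E",
    8: "CH3E", 9: "CR1E", 10: "OH1", 11: "OC", 12: "OS", 13: "CH2G",
    14: "CH2P", 15: "NH1S", 16: "NC2", 17: "NH2", 18: "CR1W", 19: "CY2",
    20: "SC", 21: "CF", 22: "SM", 23: "CY", 24: "CW", 25: "CRHH",
    26: "NH3", 27: "CR1H", 28: "C5", 29: "N", 30: "C5W", 31: "HOH",
}

#: van der Waals radius (Angstrom) per type ID
TYPE_RADII = {
    1: 1.65, 2: 1.76, 3: 1.87, 4: 1.40, 5: 1.76, 6: 1.87, 7: 1.87,
    8: 1.87, 9: 1.76, 10: 1.40, 11: 1.40, 12: 1.40, 13: 1.87, 14: 1.87,
    15: 1.65, 16: 1.65, 17: 1.65, 18: 1.76, 19: 1.76, 20: 1.85, 21: 1.76,
    22: 1.85, 23: 1.76, 24: 1.76, 25: 1.76, 26: 1.50, 27: 1.76, 28: 1.76,
    29: 1.65, 30: 1.76, 31: 1.40,
}

# Backbone typing shared by all residues (Gly CA and Pro N overridden below).
_BACKBONE = {"N": 1, "CA": 3, "C": 2, "O": 4}

# Side-chain typing per residue: atom name -> type ID.
_SIDECHAINS: dict[str, dict[str, int]] = {
    "ALA": {"CB": 8},
    "ARG": {"CB": 7, "CG": 7, "CD": 7, "NE": 15, "CZ": 5, "NH1": 16, "NH2": 16},
    "ASN": {"CB": 7, "CG": 5, "OD1": 12, "ND2": 17},
    "ASP": {"CB": 7, "CG": 5, "OD1": 11, "OD2": 11},
    "CYS": {"CB": 7, "SG": 20},
    "GLN": {"CB": 7, "CG": 7, "CD": 5, "OE1": 12, "NE2": 17},
    "GLU": {"CB": 7, "CG": 7, "CD": 5, "OE1": 11, "OE2": 11},
    "GLY": {},
    "HIS": {"CB": 7, "CG": 28, "ND1": 15, "CD2": 27, "CE1": 25, "NE2": 15},
    "ILE": {"CB": 6, "CG1": 7, "CG2": 8, "CD1": 8},
    "LEU": {"CB": 7, "CG": 6, "CD1": 8, "CD2": 8},
    "LYS": {"CB": 7, "CG": 7, "CD": 7, "CE": 7, "NZ": 26},
    "MET": {"CB": 7, "CG": 7, "SD": 22, "CE": 8},
    "PHE": {"CB": 7, "CG": 21, "CD1": 9, "CD2": 9, "CE1": 9, "CE2": 9, "CZ": 9},
    "PRO": {"CB": 14, "CG": 14, "CD": 14},
    "SER": {"CB": 7, "OG": 10},
    "THR": {"CB": 6, "OG1": 10, "CG2": 8},
    "TRP": {"CB": 7, "CG": 30, "CD1": 9, "CD2": 24, "NE1": 15, "CE2": 24,
            "CE3": 9, "CZ2": 18, "CZ3": 9, "CH2": 18},
    "TYR": {"CB": 7, "CG": 23, "CD1": 9, "CD2": 9, "CE1": 9, "CE2": 9,
            "CZ": 19, "OH": 10},
    "VAL": {"CB": 6, "CG1": 8, "CG2": 8},
}

STANDARD_RESIDUES = frozenset(_SIDECHAINS)


def _build_entries() -> dict[tuple[str, str], tuple[int, float]]:
    entries: dict[tuple[str, str], tuple[int, float]] = {}
    for res, side in _SIDECHAINS.items():
        for name, tid in _BACKBONE.items():
            entries[(res, name)] = (tid, TYPE_RADII[tid])
        for name, tid in side.items():
            entries[(res, name)] = (tid, TYPE_RADII[tid])
    # residue-context overrides
    entries[("GLY", "CA")] = (13, TYPE_RADII[13])
    entries[("PRO", "N")] = (29, TYPE_RADII[29])
    # crystal water oxygen
    entries[("HOH", "O")] = (31, TYPE_RADII[31])
    entries[("WAT", "O")] = (31, TYPE_RADII[31])
    return entries


@dataclass(frozen=True)
class AtomTypeTable:
    """Mapping (residue name, atom name) -> (type ID, vdW radius in A)."""

    entries: dict[tuple[str, str], tuple[int, float]] = field(default_factory=_build_entries)

    def lookup(self, res_name: str, atom_name: str) -> tuple[int, float] | None:
        """Return (type ID, radius) or None for atoms outside the table."""
        return self.entries.get((res_name.strip().upper(), atom_name.strip().upper()))

    def radius_of_type(self, type_id: int) -> float:
        return TYPE_RADII[type_id]

    @property
    def n_protein_entries(self) -> int:
        """Number of typed heavy atoms across the 20 standard residues."""
        return sum(1 for (res, _a) in self.entries if res in STANDARD_RESIDUES)


def default_atom_type_table() -> AtomTypeTable:
    return AtomTypeTable()
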