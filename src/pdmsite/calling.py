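"""From raw classifier activities to interface patches and residue calls.

Activities from different per-atom-type models are not directly comparable,
so each model carries a calibration table: validation activities are binned
(width 0.1) and each bin's confidence is its observed true-positive
fraction.  Confident atoms seed surface patches (seed > 0.6, members > 0.2
within 11 A, patches merged when seeds come within 10 A), and a residue is
called positive when more than 30% of its surface atoms are patch members.
The same 30% rule applied to dSASA > 0 atoms defines the residue-level
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure

__all__ = [
    "ConfidenceTable", "build_confidence_table", "to_confidence",
    "Patch", "call_patches", "ResidueCall", "residues_from_patches",
    "actual_residue_sites",
]

N_BINS = 10
SEED_THRESHOLD = 0.6
MEMBER_THRESHOLD = 0.2
GROW_RADIUS = 11.0
MERGE_DISTANCE = 10.0
RESIDUE_FRACTION = 0.3


@dataclass
class ConfidenceTable:
    """Activity-to-confidence lookup for one atom type.

    ``confidence[b]`` is the true-positive fraction among validation
    predictions whose activity fell in bin b = [b/10, (b+1)/10); empty bins
    are filled by linear interpolation between the nearest populated bins
    (edge bins copy the nearest populated value).  Raw counts are retained
    so the conservation identity sum(conf * count) == #positives holds on
    the populated bins.
    """

    confidence: np.ndarray          # (10,)
    counts: np.ndarray              # (10,) total predictions per bin
    positives: np.ndarray           # (10,) positive labels per bin

    def to_dict(self) -> dict:
        return {k: getattr(self, k).tolist() for k in ("confidence", "counts", "positives")}

    @classmethod
    def from_dict(cls, d: dict) -> "ConfidenceTable":
        return cls(confidence=np.asarray(d["confidence"], dtype=float),
                   counts=np.asarray(d["counts"], dtype=int),
                   positives=np.asarray(d["positives"], dtype=int))


def _bin_index(activity: np.ndarray) -> np.ndarray:
    return np.minimum((np.asarray(activity) * N_BINS).astype(int), N_BINS - 1)


def build_confidence_table(activities: np.ndarray, labels: np.ndarray) -> ConfidenceTable:
    """Bin validation predictions and record per-bin positive fractions."""
    activities = np.asarray(activities, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if activities.size == 0:
        raise ValueError("no validation predictions to calibrate on")
    if np.any((activities < 0) | (activities > 1)):
        raise ValueError("activities outside [0, 1]")
    bins = _bin_index(activities)
    counts = np.bincount(bins, minlength=N_BINS)
    positives = np.bincount(bins, weights=labels.astype(float), minlength=N_BINS).astype(int)
    conf = np.full(N_BINS, np.nan)
    nz = counts > 0
    conf[nz] = positives[nz] / counts[nz]
    # interpolate empty bins from nearest populated neighbours
    if not nz.all():
        populated = np.flatnonzero(nz)
        centers = (np.arange(N_BINS) + 0.5) / N_BINS
        conf = np.interp(centers, centers[populated], conf[populated])
    return ConfidenceTable(confidence=conf, counts=counts, positives=positives)


def to_confidence(activity: float | np.ndarray, table: ConfidenceTable) -> np.ndarray:
    """Bin lookup; activity 1.0 maps to the last bin."""
    activity = np.asarray(activity, dtype=float)
    if np.any((activity < 0) | (activity > 1)):
        raise ValueError("activity outside [0, 1]")
    return table.confidence[_bin_index(activity)]


@dataclass
class Patch:
    """A predicted interface patch: seed atoms plus grown membership."""

    seed_idx: list[int]
    member_idx: list[int] = field(default_factory=list)

    def center(self, coords: np.ndarray) -> np.ndarray:
        return coords[self.member_idx].mean(axis=0)


def call_patches(coords: np.ndarray, confidences: np.ndarray,
                 seed_threshold: float = SEED_THRESHOLD,
                 grow_radius: float = GROW_RADIUS,
                 member_threshold: float = MEMBER_THRESHOLD,
                 merge_distance: float = MERGE_DISTANCE) -> list[Patch]:
    """Cluster confident surface atoms into interface patches.

    Seeds are atoms with confidence strictly above ``seed_threshold``;
    each seed collects atoms within ``grow_radius`` whose confidence
    exceeds ``member_threshold``; seed groups are merged by single linkage
    (transitive closure) at ``merge_distance``.  Order-independent.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    confidences = np.asarray(confidences, dtype=float)
    seeds = np.flatnonzero(confidences > seed_threshold)
    if seeds.size == 0:
        return []
    # union-find over seeds at merge_distance (single linkage)
    parent = {int(s): int(s) for s in seeds}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    tree = cKDTree(coords[seeds])
    for ii, jj in tree.query_pairs(merge_distance):
        ra, rb = find(int(seeds[ii])), find(int(seeds[jj]))
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    groups: dict[int, list[int]] = {}
    for s in seeds:
        groups.setdefault(find(int(s)), []).append(int(s))
    eligible = np.flatnonzero(confidences > member_threshold)
    etree = cKDTree(coords[eligible])
    patches = []
    for root in sorted(groups):
        group_seeds = sorted(groups[root])
        members: set[int] = set()
        for s in group_seeds:
            members.update(int(eligible[k]) for k in
                           etree.query_ball_point(coords[s], grow_radius))
        patches.append(Patch(seed_idx=group_seeds, member_idx=sorted(members)))
    return patches


@dataclass(frozen=True)
class ResidueCall:
    residue: tuple[str, int]
    res_name: str
    predicted: bool
    actual: bool | None
    predicted_fraction: float
    actual_fraction: float | None


def _surface_census(structure: Structure) -> dict[tuple[str, int], list[int]]:
    out: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(structure.atoms):
        if a.is_surface and a.res_name not in ("HOH", "WAT"):
            out.setdefault(a.residue_key, []).append(i)
    return out


def residues_from_patches(patches: list[Patch], structure: Structure,
                          atom_indices: list[int],
                          fraction_threshold: float = RESIDUE_FRACTION) -> dict[tuple[str, int], tuple[bool, float]]:
    """Residue-level predictions from patch membership.

    ``atom_indices`` maps patch coordinate rows back to structure atom
    indices.  A residue is positive when strictly more than 30% of its
    surface atoms are patch members; fully buried residues are excluded.
    """
    member_atoms: set[int] = set()
    for p in patches:
        member_atoms.update(atom_indices[k] for k in p.member_idx)
    out: dict[tuple[str, int], tuple[bool, float]] = {}
    for rkey, idxs in _surface_census(structure).items():
        frac = sum(1 for i in idxs if i in member_atoms) / len(idxs)
        out[rkey] = (frac > fraction_threshold, frac)
    return out


def actual_residue_sites(structure: Structure,
                         fraction_threshold: float = RESIDUE_FRACTION) -> dict[tuple[str, int], tuple[bool, float]]:
    """Residue-level ground truth: same 30% rule over dSASA > 0 atoms."""
    census = _surface_census(structure)
    if not census:
        return {}
    out: dict[tuple[str, int], tuple[bool, float]] = {}
    for rkey, idxs in census.items():
        for i in idxs:
            if structure.atoms[i].dsasa is None:
                raise ValueError(f"missing dSASA for atom {structure.atoms[i].key}; "
                                 "run label_ppi_atoms first")
        frac = sum(1 for i in idxs if structure.atoms[i].is_ppi) / len(idxs)
        out[rkey] = (frac > fraction_threshold, frac)
    return out
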