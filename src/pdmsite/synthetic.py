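"""Deterministic toy structures for desk-scale pipeline experiments.

Real interface prediction needs curated complexes; these generators build
idealized "proteins" that exercise every pipeline stage instead:

* ``generate_toy_complex`` — two sheet-like chains docked along a plane.
  Chain A is a rectangular lattice of residues whose side chains (1-3
  spheres of correctly named/typed atoms) point toward the interface;
  a smaller chain B sits underneath a central footprint, so only the
  footprint residues bury area on binding.  The footprint is enriched in
  hydrophobic residues, mimicking the hydrophobic core of real interfaces.
* ``generate_reference_set`` — compact layered globules with hydrophobic
  interiors and polar surfaces, supplying interior-contact statistics for
  the knowledge base.
* ``end_to_end_scenario`` — a complete experiment (knowledge base -> PDMs
  -> features -> bagged training -> patch calling -> residue metrics) with
  planted interfaces recoverable, plus a label-shuffled null control.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import AtomSite, Structure

__all__ = ["ToyComplexSpec", "generate_toy_complex", "generate_reference_set",
           "end_to_end_scenario", "ScenarioResult"]

# lattice geometry (Angstrom)
X_SPACING = 3.8        # along-strand CA spacing
Y_SPACING = 4.8        # inter-strand spacing
SIDE_STEP = 1.5        # side-chain sphere spacing along the chain normal
BB_DZ = 0.45           # N/C offset from the CA plane, away from the side chains
INTERFACE_GAP = 2.0    # vertical tip-to-tip offset across the docking plane
INTERFACE_STAGGER = (1.9, 2.4)   # lateral knobs-into-holes offset of chain B

# side-chain builds: atom names placed at 1, 2, 3 steps from CA
SIDECHAIN_BUILD = {
    "GLY": [],
    "ALA": ["CB"],
    "VAL": ["CB", "CG1"],
    "ILE": ["CB", "CD1"],
    "SER": ["CB", "OG"],
    "THR": ["CB", "OG1"],
    "CYS": ["CB", "SG"],
    "LEU": ["CB", "CG", "CD1"],
    "MET": ["CB", "CG", "SD"],
    "PHE": ["CB", "CG", "CZ"],
    "TYR": ["CB", "CG", "CZ"],
    "TRP": ["CB", "CG", "CZ2"],
    "LYS": ["CB", "CD", "NZ"],
    "ARG": ["CB", "CZ", "NH1"],
    "GLU": ["CB", "CD", "OE1"],
    "GLN": ["CB", "CD", "OE1"],
    "ASN": ["CB", "CG", "OD1"],
    "ASP": ["CB", "CG", "OD1"],
    "HIS": ["CB", "CG", "NE2"],
}

#: long-side-chain pools used at the planted interface (tips reach the plane)
HYDROPHOBIC_LONG = ["LEU", "MET", "PHE", "TYR", "TRP"]
POLAR_LONG = ["LYS", "ARG", "GLU", "GLN", "ASN", "ASP", "HIS"]
SHORT_POOL = ["GLY", "ALA", "VAL", "ILE", "SER", "THR", "CYS"]
#: background composition: hydrophobic types stay common away from the
#: interface (as on real surfaces), so residue type alone cannot separate
#: interface from non-interface -- only hydrophobic clustering can
BACKGROUND_WEIGHTS = (0.40, 0.40, 0.20)   # hydrophobic-long, polar-long, short


@dataclass(frozen=True)
class ToyComplexSpec:
    """Study conditions for one docked toy complex."""

    a_strands: int = 8
    a_length: int = 8
    b_strands: int = 3
    b_length: int = 3
    interface_enrichment: float = 0.85   # hydrophobic fraction at the footprint
    gap: float = INTERFACE_GAP
    seed: int = 0

    def __post_init__(self):
        if min(self.a_strands, self.a_length) < 2 or min(self.b_strands, self.b_length) < 1:
            raise ValueError("chains too small to build")
        if self.b_strands > self.a_strands - 2 or self.b_length > self.a_length - 2:
            raise ValueError("partner footprint must fit inside the interior of chain A")


def _build_sheet(chain_id: str, res_names: list[list[str]], z_plane: float,
                 direction: int, xy_offset: tuple[float, float],
                 start_seq: int = 1) -> list[AtomSite]:
    """One sheet chain: strands along x, stacked along y.

    ``direction`` +1 points side chains toward +z, -1 toward -z; backbone
    N/C/O sit on the opposite side of the CA plane.
    """
    atoms: list[AtomSite] = []
    seq = start_seq
    ox, oy = xy_offset
    for s, strand in enumerate(res_names):
        for i, rname in enumerate(strand):
            ca = np.array([ox + i * X_SPACING, oy + s * Y_SPACING, z_plane])
            up = -direction  # backbone decoration side
            n = ca + np.array([-1.05, 0.0, up * BB_DZ])
            c = ca + np.array([1.05, 0.0, up * BB_DZ])
            o = c + np.array([0.0, 0.0, up * 1.25])
            atoms.append(AtomSite(chain_id, rname, seq, "N", n))
            atoms.append(AtomSite(chain_id, rname, seq, "CA", ca))
            atoms.append(AtomSite(chain_id, rname, seq, "C", c))
            atoms.append(AtomSite(chain_id, rname, seq, "O", o))
            # small lateral zigzag keeps side-chain atoms non-collinear so
            # every atom anchors a well-defined local frame
            for k, aname in enumerate(SIDECHAIN_BUILD[rname], start=1):
                zig = 1.0 if k % 2 else -1.0
                pos = ca + np.array([zig * 0.35, zig * 0.25,
                                     direction * k * SIDE_STEP])
                atoms.append(AtomSite(chain_id, rname, seq, aname, pos))
            seq += 1
    return atoms


def _check_clash_free(structure: Structure) -> None:
    """No non-bonded heavy-atom pair closer than 0.8 x vdW sum."""
    from scipy.spatial import cKDTree

    xyz = structure.coords()
    tree = cKDTree(xyz)
    bonded = {tuple(sorted(p)) for p in structure.bonded_within(2)}
    for i, j in tree.query_pairs(3.0):
        if (min(i, j), max(i, j)) in bonded:
            continue
        a, b = structure.atoms[i], structure.atoms[j]
        ra = a.radius if a.radius is not None else 1.87
        rb = b.radius if b.radius is not None else 1.87
        if np.linalg.norm(a.xyz - b.xyz) < 0.8 * (ra + rb):
            raise ValueError(f"steric clash between {a.key} and {b.key}")


def generate_toy_complex(spec: ToyComplexSpec):
    """Build (unbound chain A, complexed A+B, interface residue keys).

    The planted interface is the set of chain-A residues directly above the
    chain-B footprint; their side-chain tips reach the docking plane and
    bury area on binding.  Deterministic under the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    # footprint: random block of interior lattice positions, so interface
    # location carries no information a predictor could exploit
    s0 = int(rng.integers(1, spec.a_strands - spec.b_strands))
    i0 = int(rng.integers(1, spec.a_length - spec.b_length))
    footprint = {(s, i) for s in range(s0, s0 + spec.b_strands)
                 for i in range(i0, i0 + spec.b_length)}

    def draw_interface() -> str:
        if rng.random() < spec.interface_enrichment:
            return str(rng.choice(HYDROPHOBIC_LONG))
        return str(rng.choice(POLAR_LONG))

    def draw_background() -> str:
        r = rng.random()
        w_h, w_p, _w_s = BACKGROUND_WEIGHTS
        if r < w_h:
            return str(rng.choice(HYDROPHOBIC_LONG))
        if r < w_h + w_p:
            return str(rng.choice(POLAR_LONG))
        return str(rng.choice(SHORT_POOL))

    a_names: list[list[str]] = []
    for s in range(spec.a_strands):
        strand = []
        for i in range(spec.a_length):
            if (s, i) in footprint:
                strand.append(draw_interface())
            else:
                strand.append(draw_background())
        a_names.append(strand)
    b_names = [[draw_interface() for _ in range(spec.b_length)]
               for _ in range(spec.b_strands)]

    a_atoms = _build_sheet("A", a_names, z_plane=0.0, direction=-1, xy_offset=(0.0, 0.0))
    # B docks underneath the footprint, side chains up, tips interdigitated
    # with A's (laterally staggered, vertically overlapping by spec.gap)
    tip_a = -3 * SIDE_STEP
    z_b = tip_a - spec.gap - 3 * SIDE_STEP
    b_xy = (i0 * X_SPACING + INTERFACE_STAGGER[0],
            s0 * Y_SPACING + INTERFACE_STAGGER[1])
    b_atoms = _build_sheet("B", b_names, z_plane=z_b, direction=+1, xy_offset=b_xy)

    def clone(sites: list[AtomSite]) -> list[AtomSite]:
        return [AtomSite(a.chain, a.res_name, a.res_seq, a.atom_name, a.xyz.copy())
                for a in sites]

    unbound = Structure(clone(a_atoms), provenance=f"toy-complex seed={spec.seed} chain A")
    complexed = Structure(clone(a_atoms) + clone(b_atoms),
                          provenance=f"toy-complex seed={spec.seed} chains A+B")
    _check_clash_free(complexed)
    # interface residue keys of chain A (1-based sequence numbering)
    interface = {("A", s * spec.a_length + i + 1) for (s, i) in footprint}
    return unbound, complexed, interface


def generate_reference_set(n: int, seed: int = 0, layers: int = 3,
                           strands: int = 5, length: int = 5) -> list[Structure]:
    """Compact layered toy globules with hydrophobic interiors.

    Sheets are stacked along z with every layer's side chains pointing up
    into the gap below the next layer (the top layer's chains face the
    solvent), laterally staggered on alternate layers.  Side chains of
    central positions in the lower layers end up solvent-inaccessible:
    those buried positions draw mostly hydrophobic residues and the exposed
    ones mostly polar, mirroring how real protein interiors supply the
    contact statistics.
    """
    if n < 1:
        raise ValueError("need at least one reference structure")
    out = []
    layer_dz = 7.0
    for k in range(n):
        rng = np.random.default_rng((seed, k))
        atoms: list[AtomSite] = []
        seq_base = 0
        for lz in range(layers):
            names = []
            for s in range(strands):
                strand = []
                for i in range(length):
                    buried = (lz < layers - 1 and 0 < s < strands - 1
                              and 0 < i < length - 1)
                    hydro_p = 0.85 if buried else 0.25
                    if rng.random() < hydro_p:
                        strand.append(str(rng.choice(HYDROPHOBIC_LONG)))
                    else:
                        strand.append(str(rng.choice(POLAR_LONG)))
                names.append(strand)
            off = (1.9 * (lz % 2), 2.4 * (lz % 2))
            atoms.extend(_build_sheet("A", names, z_plane=lz * layer_dz,
                                      direction=+1, xy_offset=off,
                                      start_seq=seq_base + 1))
            seq_base += strands * length
        out.append(Structure(atoms, provenance=f"toy-globule seed=({seed},{k})"))
    return out


# --------------------------------------------------------------------------
# end-to-end scenario
# --------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """Outcome of the desk-scale planted-interface experiment."""

    residue_mcc: float
    residue_counts: "object"
    atom_mcc: float
    n_atoms: int
    null_residue_mcc: float | None
    n_ensembles: int
    n_test_proteins: int
    per_protein: list[dict] = field(default_factory=list)


def _prepare_protein(unbound: Structure, complexed: Structure, kb, n_sasa_points: int):
    """Type, label, grid and featurize one toy complex; returns a dict."""
    from .atom_types import default_atom_type_table
    from .features import compute_raw_features
    from .grids import compute_occupancy, grid_for_structure, project_pdms
    from .sasa import compute_sasa
    from .structure import assign_atom_types, label_ppi_atoms, select_prediction_atoms

    table = default_atom_type_table()
    assign_atom_types(unbound, table)
    assign_atom_types(complexed, table)
    compute_sasa(unbound, n_points=n_sasa_points)
    compute_sasa(complexed, n_points=n_sasa_points)
    label_ppi_atoms(unbound, complexed)
    predictable = select_prediction_atoms(unbound)
    spec = grid_for_structure(unbound)
    occ = compute_occupancy(unbound, spec)
    grid = project_pdms(unbound, kb, spec, occupancy=occ)
    raw = compute_raw_features(unbound, grid, occ, predictable)
    labels = np.array([unbound.atoms[i].is_ppi for i in predictable], dtype=bool)
    types = np.array([unbound.atoms[i].type_id for i in predictable], dtype=int)
    return {"structure": unbound, "predictable": predictable, "raw": raw,
            "labels": labels, "types": types}


def _train_ensembles(train_proteins: list[dict], constants, seed: int,
                     n_bags: int, shuffle_labels: bool = False,
                     n_rotations: int = 3):
    """Per-type bagged ANN ensembles with thresholds and confidence tables.

    Each atom type's pooled examples are split into ``n_rotations``
    stratified folds.  Every rotation trains a bagged ensemble on the
    out-of-fold data and predicts its validation fold, so each example is
    validated exactly once; the activity-to-confidence table and the
    decision threshold are calibrated on the pooled validation predictions
    and the deployed ensemble is the rotation with the best validation MCC.
    """
    from .calling import build_confidence_table
    from .ensemble import AtomTypeEnsemble, make_bags, train_ann_bag
    from .features import scale_feature
    from .metrics import make_cv_folds, mcc_from_labels, optimize_threshold

    rng = np.random.default_rng(seed)
    feats = np.vstack([scale_feature(p["raw"], constants) for p in train_proteins])
    labels = np.concatenate([p["labels"] for p in train_proteins])
    if shuffle_labels:
        # permutation null: shuffle the label column over the pooled
        # training examples, destroying both the feature-label association
        # and the per-atom-type burial rates
        labels = labels.copy()
        rng.shuffle(labels)
    types = np.concatenate([p["types"] for p in train_proteins])
    ensembles: dict[int, AtomTypeEnsemble] = {}
    for t in sorted(set(types.tolist())):
        sel = np.flatnonzero(types == t)
        y = labels[sel].copy()
        x = feats[sel]
        if int(y.sum()) < 2 * n_rotations or int((~y).sum()) < 2 * n_rotations:
            continue
        rs = np.random.default_rng((seed, t))
        plan = make_cv_folds(y, k=n_rotations, seed=int(rs.integers(2 ** 31)))
        pooled_act, pooled_lab = [], []
        best: tuple[float, AtomTypeEnsemble] | None = None
        for r in range(n_rotations):
            val_idx = list(plan.folds[r])
            tr_idx = [i for f in range(n_rotations) if f != r for i in plan.folds[f]]
            xtr, ytr = x[tr_idx], y[tr_idx]
            xval, yval = x[val_idx], y[val_idx]
            bags = make_bags(np.flatnonzero(ytr), np.flatnonzero(~ytr),
                             n_bags=n_bags, seed=int(rs.integers(2 ** 31)))
            members = [train_ann_bag(xtr, ytr, bag, xval, yval,
                                     seed=int(rs.integers(2 ** 31)))
                       for bag in bags]
            ens = AtomTypeEnsemble(type_id=t, algorithm="ann", members=members)
            val_act = ens.predict(xval)
            pooled_act.append(val_act)
            pooled_lab.append(yval)
            mcc = mcc_from_labels(yval, val_act >= 0.5)
            if best is None or mcc > best[0] + 1e-12:
                best = (mcc, ens)
        act = np.concatenate(pooled_act)
        lab = np.concatenate(pooled_lab)
        ens = best[1]
        try:
            ens.threshold, _ = optimize_threshold(act, lab)
        except ValueError:
            ens.threshold = 0.5
        ens.confidence_table = build_confidence_table(act, lab)
        ensembles[t] = ens
    return ensembles


def predict_protein(protein: dict, ensembles: dict, constants):
    """Activities, confidences, patches and residue calls for one protein."""
    from .calling import call_patches, residues_from_patches, to_confidence
    from .features import scale_feature

    feats = scale_feature(protein["raw"], constants)
    n = len(protein["predictable"])
    activity = np.zeros(n)
    confidence = np.zeros(n)
    predicted_atom = np.zeros(n, dtype=bool)
    for t in sorted(set(protein["types"].tolist())):
        sel = np.flatnonzero(protein["types"] == t)
        if t not in ensembles:
            continue
        ens = ensembles[t]
        act = ens.predict(feats[sel])
        activity[sel] = act
        confidence[sel] = to_confidence(act, ens.confidence_table)
        predicted_atom[sel] = act >= ens.threshold
    coords = np.array([protein["structure"].atoms[i].xyz for i in protein["predictable"]])
    patches = call_patches(coords, confidence) if n else []
    residue_pred = residues_from_patches(patches, protein["structure"],
                                         protein["predictable"])
    return {"activity": activity, "confidence": confidence,
            "predicted_atom": predicted_atom, "patches": patches,
            "residue_pred": residue_pred}


def end_to_end_scenario(seed: int = 0, n_train: int = 14, n_test: int = 8,
                        n_reference: int = 8, n_bags: int = 10,
                        n_sasa_points: int = 256,
                        include_null: bool = True) -> ScenarioResult:
    """Run the whole pipeline on planted-interface toys and benchmark it.

    Residue-level confusion counts are pooled over the test proteins; the
    null control retrains with per-type label-shuffled training data and
    evaluates against the true interfaces.
    """
    from .calling import actual_residue_sites
    from .features import fit_normalization
    from .kb import build_knowledge_base
    from .metrics import ConfusionCounts, compute_metrics, confusion_from_labels

    root = np.random.default_rng(seed)
    ref_seed, cx_seed, train_seed = (int(root.integers(2 ** 31)) for _ in range(3))

    refs = generate_reference_set(n_reference, seed=ref_seed)
    from .atom_types import default_atom_type_table
    from .sasa import compute_sasa
    from .structure import assign_atom_types

    table = default_atom_type_table()
    for st in refs:
        assign_atom_types(st, table)
        compute_sasa(st, n_points=n_sasa_points)
    kb = build_knowledge_base(refs)

    proteins = []
    for k in range(n_train + n_test):
        spec = ToyComplexSpec(seed=cx_seed + k)
        unbound, complexed, interface = generate_toy_complex(spec)
        p = _prepare_protein(unbound, complexed, kb, n_sasa_points)
        p["interface"] = interface
        proteins.append(p)
    train_proteins, test_proteins = proteins[:n_train], proteins[n_train:]

    constants = fit_normalization([p["raw"] for p in train_proteins])
    ensembles = _train_ensembles(train_proteins, constants, train_seed, n_bags)

    def evaluate(ens) -> tuple:
        actual_all, pred_all = [], []
        atom_actual, atom_pred = [], []
        per_protein = []
        for p in test_proteins:
            res = predict_protein(p, ens, constants)
            truth = actual_residue_sites(p["structure"])
            for rkey, (act, _frac) in truth.items():
                actual_all.append(act)
                pred_all.append(res["residue_pred"].get(rkey, (False, 0.0))[0])
            atom_actual.extend(p["labels"].tolist())
            atom_pred.extend(res["predicted_atom"].tolist())
            per_protein.append({"n_patches": len(res["patches"]),
                                "mean_confidence": float(np.mean(res["confidence"]))
                                if len(res["confidence"]) else 0.0})
        counts = confusion_from_labels(np.array(actual_all), np.array(pred_all))
        res_mcc = compute_metrics(counts).mcc
        atom_counts = confusion_from_labels(np.array(atom_actual), np.array(atom_pred))
        atom_mcc = compute_metrics(atom_counts).mcc if atom_counts.total else 0.0
        return res_mcc, counts, atom_mcc, atom_counts.total, per_protein

    res_mcc, counts, atom_mcc, n_atoms, per_protein = evaluate(ensembles)

    null_mcc = None
    if include_null:
        null_ens = _train_ensembles(train_proteins, constants, train_seed,
                                    n_bags, shuffle_labels=True)
        null_mcc, _, _, _, _ = evaluate(null_ens)

    return ScenarioResult(residue_mcc=res_mcc, residue_counts=counts,
                          atom_mcc=atom_mcc, n_atoms=n_atoms,
                          null_residue_mcc=null_mcc,
                          n_ensembles=len(ensembles), n_test_proteins=n_test,
                          per_protein=per_protein)
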