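"""Run orchestration: file-based training and prediction pipelines.

A run is fully determined by its :class:`RunConfig` plus the input files;
every output directory carries the serialized config as a fingerprint.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .atom_types import default_atom_type_table
from .calling import actual_residue_sites, call_patches, residues_from_patches, to_confidence
from .features import (NormalizationConstants, compute_raw_features,
                       fit_normalization, scale_feature)
from .filters import load_filter_matrix, permissive_filter_matrix
from .grids import compute_occupancy, grid_for_structure, project_pdms
from .kb import ContactRule, KnowledgeBase, build_knowledge_base
from .metrics import compute_metrics, confusion_from_labels
from .sasa import compute_sasa
from .structure import (Structure, assign_atom_types, label_ppi_atoms,
                        parse_structure, select_prediction_atoms, write_atom_table)

__all__ = ["RunConfig", "build_kb_from_files", "prepare_labeled_protein",
           "run_training_pipeline", "run_prediction_pipeline", "load_model_bundle"]


@dataclass
class RunConfig:
    """Stage parameters; defaults are the documented pipeline settings."""

    seed: int = 0
    algorithm: str = "ann"            # "ann" | "svm"
    n_bags: int = 10
    negative_ratio: float = 1.5
    contact_tolerance: float = 1.4
    strict_interior: bool = True
    kb_spacing: float = 1.0
    kb_extent: float = 8.0
    grid_spacing: float = 1.0
    grid_margin: float = 6.0
    density_radius: float = 5.0
    patch_radius: float = 10.0
    sasa_points: int = 960
    probe_radius: float = 1.4
    filter_table: str | None = None
    n_rotations: int = 3

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**(yaml.safe_load(text) or {}))

    def fingerprint(self) -> str:
        import hashlib

        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _load_structure(path: Path, chains: set[str] | None, config: RunConfig) -> Structure:
    st = parse_structure(Path(path).read_text(), chains=chains)
    assign_atom_types(st, default_atom_type_table())
    compute_sasa(st, probe_radius=config.probe_radius, n_points=config.sasa_points)
    return st


def build_kb_from_files(reference_paths: list[Path], config: RunConfig) -> KnowledgeBase:
    """Parse, type and label the reference structures, then build the KB."""
    refs = [_load_structure(p, None, config) for p in reference_paths]
    fm = (load_filter_matrix(Path(config.filter_table).read_text())
          if config.filter_table else permissive_filter_matrix())
    return build_knowledge_base(refs, fm, ContactRule(config.contact_tolerance),
                                spacing=config.kb_spacing, extent=config.kb_extent,
                                strict_interior=config.strict_interior)


def prepare_labeled_protein(unbound_path: Path, complex_path: Path | None,
                            kb: KnowledgeBase, config: RunConfig,
                            chains: set[str] | None = None) -> dict:
    """Featurize one protein; labels attached when a complex is supplied."""
    unbound = _load_structure(unbound_path, chains, config)
    if complex_path is not None:
        complexed = _load_structure(complex_path, None, config)
        label_ppi_atoms(unbound, complexed)
    predictable = select_prediction_atoms(unbound)
    spec = grid_for_structure(unbound, config.grid_spacing, config.grid_margin)
    occ = compute_occupancy(unbound, spec)
    grid = project_pdms(unbound, kb, spec, occupancy=occ)
    raw = compute_raw_features(unbound, grid, occ, predictable,
                               config.density_radius, config.patch_radius)
    out = {"structure": unbound, "predictable": predictable, "raw": raw,
           "types": np.array([unbound.atoms[i].type_id for i in predictable], dtype=int)}
    if complex_path is not None:
        out["labels"] = np.array([unbound.atoms[i].is_ppi for i in predictable], dtype=bool)
    return out


def run_training_pipeline(reference_paths: list[Path],
                          training_pairs: list[tuple[Path, Path]],
                          out_dir: Path, config: RunConfig) -> dict:
    """Build KB, featurize labeled proteins, train per-type ensembles.

    Persists the KB, normalization constants, every trained ensemble (JSON)
    and the config fingerprint under ``out_dir``; returns a report dict.
    """
    from .synthetic import _train_ensembles

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for u, c in training_pairs:
        if not Path(c).exists():
            raise FileNotFoundError(f"missing complex structure for training protein {u}")
    kb = build_kb_from_files(reference_paths, config)
    kb.save(out_dir / "kb.npz")
    proteins = [prepare_labeled_protein(u, c, kb, config) for u, c in training_pairs]
    constants = fit_normalization([p["raw"] for p in proteins])
    constants.save(out_dir / "normalization.json")
    if config.algorithm != "ann":
        warnings.warn("file-based training currently persists ANN ensembles only; "
                      "using ann")
    ensembles = _train_ensembles(proteins, constants, config.seed, config.n_bags,
                                 n_rotations=config.n_rotations)
    models_dir = out_dir / "models"
    models_dir.mkdir(exist_ok=True)
    for t, ens in ensembles.items():
        (models_dir / f"type_{t:02d}.json").write_text(json.dumps(ens.to_dict()))
    (out_dir / "config.yaml").write_text(config.to_yaml())
    report = {"n_ensembles": len(ensembles),
              "ensemble_types": sorted(ensembles),
              "n_training_proteins": len(proteins),
              "kb_observations": kb.total_count(),
              "config_fingerprint": config.fingerprint()}
    (out_dir / "training_report.json").write_text(json.dumps(report, indent=2))
    return report


def load_model_bundle(model_dir: Path):
    """(kb, constants, ensembles) from a training-pipeline output directory."""
    from .ensemble import AtomTypeEnsemble

    model_dir = Path(model_dir)
    kb = KnowledgeBase.load(model_dir / "kb.npz")
    constants = NormalizationConstants.load(model_dir / "normalization.json")
    ensembles = {}
    for p in sorted((model_dir / "models").glob("type_*.json")):
        ens = AtomTypeEnsemble.from_dict(json.loads(p.read_text()))
        ensembles[ens.type_id] = ens
    return kb, constants, ensembles


def run_prediction_pipeline(query_paths: list[Path], model_dir: Path,
                            out_dir: Path, config: RunConfig,
                            complex_paths: list[Path] | None = None) -> dict:
    """Predict interface patches and residues for query structures.

    When matching complex structures are supplied the predictions are also
    benchmarked against the dSASA-derived truth.
    """
    kb, constants, ensembles = load_model_bundle(model_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(config.to_yaml())
    all_actual, all_pred = [], []
    per_protein = []
    for qi, qpath in enumerate(query_paths):
        cpath = complex_paths[qi] if complex_paths else None
        p = prepare_labeled_protein(qpath, cpath, kb, config)
        feats = scale_feature(p["raw"], constants)
        n = len(p["predictable"])
        if n == 0:
            warnings.warn(f"{qpath}: no predictable atoms; empty prediction")
        activity = np.zeros(n)
        confidence = np.zeros(n)
        for t in sorted(set(p["types"].tolist())):
            if t not in ensembles:
                continue
            sel = np.flatnonzero(p["types"] == t)
            act = ensembles[t].predict(feats[sel])
            activity[sel] = act
            confidence[sel] = to_confidence(act, ensembles[t].confidence_table)
        coords = np.array([p["structure"].atoms[i].xyz for i in p["predictable"]])
        patches = call_patches(coords, confidence) if n else []
        residue_pred = residues_from_patches(patches, p["structure"], p["predictable"])
        stem = Path(qpath).stem
        write_atom_table(p["structure"], out_dir / f"{stem}_atoms.tsv")
        _write_predictions(out_dir / f"{stem}_predictions.tsv", p, activity,
                           confidence, patches, residue_pred)
        entry = {"query": str(qpath), "n_predictable": n, "n_patches": len(patches)}
        if cpath is not None:
            truth = actual_residue_sites(p["structure"])
            actual = [truth[k][0] for k in sorted(truth)]
            pred = [residue_pred.get(k, (False, 0.0))[0] for k in sorted(truth)]
            all_actual.extend(actual)
            all_pred.extend(pred)
            counts = confusion_from_labels(np.array(actual), np.array(pred))
            entry["residue_mcc"] = compute_metrics(counts).mcc if counts.total else 0.0
        per_protein.append(entry)
    report: dict = {"proteins": per_protein,
                    "config_fingerprint": config.fingerprint()}
    if all_actual:
        counts = confusion_from_labels(np.array(all_actual), np.array(all_pred))
        m = compute_metrics(counts)
        report["residue_benchmark"] = {
            "mcc": m.mcc, "accuracy": m.accuracy, "precision": m.precision,
            "sensitivity": m.sensitivity, "specificity": m.specificity,
            "f_score": m.f_score,
            "tp": counts.tp, "tn": counts.tn, "fp": counts.fp, "fn": counts.fn,
        }
    (out_dir / "prediction_report.json").write_text(json.dumps(report, indent=2))
    return report


def cross_validate_atoms(proteins: list[dict], config: RunConfig,
                         k: int = 5) -> dict:
    """k-fold atom-level cross validation per atom type.

    For each type, examples are split into k stratified folds; rotation r
    trains bagged members on the non-test, non-validation folds, picks the
    decision threshold on the validation fold, and predicts the test fold,
    so every example is tested exactly once.  Returns pooled confusion
    counts/metrics and the per-rotation MCC average.
    """
    from .ensemble import AtomTypeEnsemble, make_bags, train_ann_bag
    from .features import fit_normalization, scale_feature
    from .metrics import make_cv_folds, optimize_threshold

    constants = fit_normalization([p["raw"] for p in proteins])
    feats = np.vstack([scale_feature(p["raw"], constants) for p in proteins])
    labels = np.concatenate([p["labels"] for p in proteins])
    types = np.concatenate([p["types"] for p in proteins])
    rng = np.random.default_rng(config.seed)
    actual = []
    predicted = []
    fold_mccs: list[float] = []
    for t in sorted(set(types.tolist())):
        sel = np.flatnonzero(types == t)
        x, y = feats[sel], labels[sel]
        if int(y.sum()) < k or int((~y).sum()) < k:
            continue
        plan = make_cv_folds(y, k=k, seed=int(rng.integers(2 ** 31)))
        for r in range(k):
            test_idx, val_idx, train_idx = plan.rotation(r)
            bags = make_bags(np.flatnonzero(y[train_idx]),
                             np.flatnonzero(~y[train_idx]),
                             n_bags=config.n_bags, ratio=config.negative_ratio,
                             seed=int(rng.integers(2 ** 31)))
            members = [train_ann_bag(x[train_idx], y[train_idx], b,
                                     x[val_idx], y[val_idx],
                                     seed=int(rng.integers(2 ** 31)))
                       for b in bags]
            ens = AtomTypeEnsemble(t, "ann", members)
            try:
                ens.threshold, _ = optimize_threshold(ens.predict(x[val_idx]),
                                                      y[val_idx])
            except ValueError:
                ens.threshold = 0.5
            pred = ens.predict(x[test_idx]) >= ens.threshold
            actual.extend(y[test_idx].tolist())
            predicted.extend(pred.tolist())
            fc = confusion_from_labels(y[test_idx], pred)
            if fc.total:
                fold_mccs.append(compute_metrics(fc).mcc)
    counts = confusion_from_labels(np.array(actual), np.array(predicted))
    m = compute_metrics(counts)
    return {"pooled": {"mcc": m.mcc, "accuracy": m.accuracy,
                       "precision": m.precision, "sensitivity": m.sensitivity,
                       "specificity": m.specificity, "f_score": m.f_score,
                       "tp": counts.tp, "tn": counts.tn, "fp": counts.fp,
                       "fn": counts.fn},
            "mean_fold_mcc": float(np.mean(fold_mccs)) if fold_mccs else 0.0,
            "n_folds_evaluated": len(fold_mccs)}


def _write_predictions(path: Path, protein: dict, activity, confidence,
                       patches, residue_pred) -> None:
    import pandas as pd

    patch_of = {}
    for pid, patch in enumerate(patches):
        for k in patch.member_idx:
            patch_of[protein["predictable"][k]] = pid
    rows = []
    for r, i in enumerate(protein["predictable"]):
        a = protein["structure"].atoms[i]
        rows.append({"chain": a.chain, "res_seq": a.res_seq, "res_name": a.res_name,
                     "atom_name": a.atom_name, "type_id": a.type_id,
                     "activity": activity[r], "confidence": confidence[r],
                     "patch_id": patch_of.get(i, -1),
                     "residue_predicted": residue_pred.get(a.residue_key, (False, 0.0))[0]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
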