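"""Bagged per-atom-type classifiers.

Interface atoms are heavily outnumbered by the rest of the surface, so each
of the 10 bags keeps every positive example and draws 1.5x as many
negatives without replacement; the ensemble activity is the equal-weight
mean of the member outputs.  Members are either the in-package ANN or an
RBF-kernel SVM (scikit-learn, Platt-calibrated probabilities) whose cost
and gamma are grid-searched for the best internal cross-validation MCC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ann import AnnConfig, AnnModel, train_ann
from .metrics import mcc_from_labels

__all__ = [
    "TrainingBag", "make_bags", "train_ann_bag", "train_svm_bag",
    "AtomTypeEnsemble", "predict_activity", "default_svm_grid",
]

N_BAGS = 10
NEGATIVE_RATIO = 1.5


@dataclass(frozen=True)
class TrainingBag:
    """All positives plus a without-replacement negative sample."""

    positive_idx: tuple[int, ...]
    negative_idx: tuple[int, ...]

    @property
    def indices(self) -> np.ndarray:
        return np.concatenate([self.positive_idx, self.negative_idx]).astype(int)


def make_bags(positive_idx: np.ndarray, negative_idx: np.ndarray,
              n_bags: int = N_BAGS, ratio: float = NEGATIVE_RATIO,
              seed: int = 0) -> list[TrainingBag]:
    """Deterministic bag construction under a seed."""
    positive_idx = np.asarray(positive_idx, dtype=int)
    negative_idx = np.asarray(negative_idx, dtype=int)
    if len(positive_idx) == 0:
        raise ValueError("no positive examples; atom type is untrainable")
    want = int(np.ceil(ratio * len(positive_idx)))
    if want > len(negative_idx):
        warnings.warn(f"only {len(negative_idx)} negatives available for "
                      f"{len(positive_idx)} positives; using all of them in every bag")
        want = len(negative_idx)
    rng = np.random.default_rng(seed)
    bags = []
    for _ in range(n_bags):
        neg = rng.choice(negative_idx, size=want, replace=False)
        bags.append(TrainingBag(tuple(int(i) for i in positive_idx),
                                tuple(int(i) for i in neg)))
    return bags


def train_ann_bag(features: np.ndarray, labels: np.ndarray, bag: TrainingBag,
                  val_x: np.ndarray, val_y: np.ndarray, seed: int = 0,
                  config: AnnConfig | None = None) -> AnnModel:
    idx = bag.indices
    return train_ann(features[idx], labels[idx], val_x, val_y, seed=seed, config=config)


def default_svm_grid() -> list[tuple[float, float]]:
    """(cost, gamma) grid: c in 2^-5..2^15, gamma in 2^-15..2^3, step 2^2."""
    cs = [2.0 ** e for e in range(-5, 16, 2)]
    gs = [2.0 ** e for e in range(-15, 4, 2)]
    return [(c, g) for c in cs for g in gs]


def train_svm_bag(features: np.ndarray, labels: np.ndarray, bag: TrainingBag,
                  grid: list[tuple[float, float]] | None = None,
                  seed: int = 0, n_inner_folds: int = 3):
    """RBF SVM with (c, gamma) chosen by internal CV MCC on the bag.

    Ties break to the smallest cost, then smallest gamma.  Returns a fitted
    Platt-calibrated SVC (sigmoid calibration on the bag).
    """
    from sklearn.calibration import CalibratedClassifierCV
    from sklearn.model_selection import StratifiedKFold
    from sklearn.svm import SVC

    grid = grid or default_svm_grid()
    if not grid:
        raise ValueError("empty parameter grid")
    idx = bag.indices
    x, y = features[idx], np.asarray(labels, dtype=bool)[idx]
    best = None
    grid_sorted = sorted(grid)
    skf = StratifiedKFold(n_splits=n_inner_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))
    for c, g in grid_sorted:
        preds = np.zeros(len(y), dtype=bool)
        for tr, te in splits:
            clf = SVC(C=c, gamma=g, kernel="rbf", random_state=seed)
            clf.fit(x[tr], y[tr])
            preds[te] = clf.predict(x[te]).astype(bool)
        mcc = mcc_from_labels(y, preds)
        if best is None or mcc > best[0] + 1e-12:
            best = (mcc, c, g)
    _, c, g = best
    model = CalibratedClassifierCV(SVC(C=c, gamma=g, kernel="rbf",
                                       random_state=seed),
                                   method="sigmoid", cv=n_inner_folds,
                                   ensemble=False)
    model.fit(x, y)
    return model


@dataclass
class AtomTypeEnsemble:
    """Bagged classifier for one protein atom type."""

    type_id: int
    algorithm: str                        # "ann" | "svm"
    members: list = field(default_factory=list)
    threshold: float = 0.5
    confidence_table: "object | None" = None    # calling.ConfidenceTable

    def predict(self, features: np.ndarray) -> np.ndarray:
        return predict_activity(self, features)

    def to_dict(self) -> dict:
        if self.algorithm != "ann":
            raise NotImplementedError("only ANN ensembles serialize to JSON")
        return {
            "type_id": self.type_id,
            "algorithm": self.algorithm,
            "threshold": self.threshold,
            "members": [m.params() for m in self.members],
            "confidence_table": (self.confidence_table.to_dict()
                                 if self.confidence_table is not None else None),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AtomTypeEnsemble":
        from .calling import ConfidenceTable

        ens = cls(type_id=d["type_id"], algorithm=d["algorithm"],
                  members=[AnnModel.from_params(p) for p in d["members"]],
                  threshold=d["threshold"])
        if d.get("confidence_table") is not None:
            ens.confidence_table = ConfidenceTable.from_dict(d["confidence_table"])
        return ens


def predict_activity(ensemble: AtomTypeEnsemble, features: np.ndarray) -> np.ndarray:
    """Equal-weight mean of member outputs, one activity in [0,1] per row."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != 32:
        raise ValueError(f"feature vectors must have 32 components, got {features.shape[1]}")
    if not np.all(np.isfinite(features)):
        bad = np.flatnonzero(~np.isfinite(features).all(axis=1))
        raise ValueError(f"non-finite feature component for atom row(s) {bad[:5].tolist()}")
    if not ensemble.members:
        raise ValueError("ensemble has no trained members")
    outs = []
    for m in ensemble.members:
        if hasattr(m, "predict_proba"):       # sklearn SVC
            outs.append(m.predict_proba(features)[:, list(m.classes_).index(True)])
        else:
            outs.append(m.predict(features))
    return np.mean(outs, axis=0)
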