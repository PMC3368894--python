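"""Benchmark metrics, decision-threshold optimization, cross-validation
partitioning and the rank-sum attribute-discrimination matrix.

Metrics follow the standard confusion-matrix definitions; MCC uses the
zero-denominator -> 0 convention so degenerate predictors score as random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .atom_types import N_PROTEIN_TYPES

__all__ = [
    "ConfusionCounts", "MetricReport", "compute_metrics", "confusion_from_labels",
    "mcc_from_labels", "optimize_threshold", "CvPlan", "make_cv_folds",
    "utest_matrix", "write_utest_tsv",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f_score: float
    mcc: float


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Accuracy, precision, sensitivity, specificity, F-score and MCC."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    acc = (tp + tn) / counts.total
    pre = tp / (tp + fp) if tp + fp else 0.0
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    f = 2 * pre * sen / (pre + sen) if pre + sen else 0.0
    den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    return MetricReport(acc, pre, sen, spe, f, mcc)


def confusion_from_labels(actual: np.ndarray, predicted: np.ndarray) -> ConfusionCounts:
    actual = np.asarray(actual, dtype=bool)
    predicted = np.asarray(predicted, dtype=bool)
    if actual.shape != predicted.shape:
        raise ValueError("label arrays differ in shape")
    return ConfusionCounts(
        tp=int(np.sum(actual & predicted)),
        tn=int(np.sum(~actual & ~predicted)),
        fp=int(np.sum(~actual & predicted)),
        fn=int(np.sum(actual & ~predicted)),
    )


def mcc_from_labels(actual: np.ndarray, predicted: np.ndarray) -> float:
    return compute_metrics(confusion_from_labels(actual, predicted)).mcc


def optimize_threshold(activities: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Activity threshold (predict positive when activity >= threshold)
    maximizing MCC on a validation set; ties break to the lowest threshold.

    Returns (threshold, mcc at threshold).  Raises on single-class input.
    """
    activities = np.asarray(activities, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("validation set contains a single class; "
                         "fall back to the default threshold 0.5")
    candidates = np.unique(activities)
    best_thr, best_mcc = candidates[0], -2.0
    for thr in candidates:
        m = mcc_from_labels(labels, activities >= thr)
        if m > best_mcc + 1e-15:
            best_thr, best_mcc = float(thr), m
    return best_thr, best_mcc


@dataclass(frozen=True)
class CvPlan:
    """k stratified folds with rotating test/validation/training roles."""

    folds: tuple[tuple[int, ...], ...]

    @property
    def k(self) -> int:
        return len(self.folds)

    def rotation(self, r: int) -> tuple[list[int], list[int], list[int]]:
        """(test, validation, training) index lists for rotation r."""
        k = self.k
        test = list(self.folds[r % k])
        val = list(self.folds[(r + 1) % k])
        train: list[int] = []
        for f in range(k):
            if f not in (r % k, (r + 1) % k):
                train.extend(self.folds[f])
        return test, val, train


def make_cv_folds(labels: np.ndarray, k: int = 5, seed: int = 0) -> CvPlan:
    """Stratified random partition into k folds of near-equal size."""
    labels = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    cursor = 0   # continues across classes so fold sizes differ by <= 1
    for cls in (True, False):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls} has {len(idx)} member(s), fewer than k={k}")
        rng.shuffle(idx)
        for i in idx:
            folds[cursor % k].append(int(i))
            cursor += 1
    return CvPlan(folds=tuple(tuple(sorted(f)) for f in folds))


def utest_matrix(features_by_type: dict[int, tuple[np.ndarray, np.ndarray]],
                 n_features: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Rank-sum discrimination matrix over (protein atom type, attribute).

    ``features_by_type[t]`` holds (feature matrix, boolean PPI labels) for
    atoms of type t.  Returns (p-values, signs): p is the two-sided
    Mann-Whitney p-value comparing the attribute between PPI and non-PPI
    atoms (NaN when a group is empty); sign is +1/-1/0 for the direction of
    the mean difference (PPI minus non-PPI).
    """
    p = np.full((N_PROTEIN_TYPES, n_features), np.nan)
    sign = np.zeros((N_PROTEIN_TYPES, n_features))
    for t, (feats, labels) in features_by_type.items():
        labels = np.asarray(labels, dtype=bool)
        pos, neg = feats[labels], feats[~labels]
        if len(pos) == 0 or len(neg) == 0:
            continue
        for j in range(feats.shape[1]):
            a, b = pos[:, j], neg[:, j]
            if np.ptp(np.concatenate([a, b])) == 0:
                p[t - 1, j] = 1.0
                sign[t - 1, j] = 0.0
                continue
            method = "exact" if min(len(a), len(b)) < 10 else "asymptotic"
            try:
                res = mannwhitneyu(a, b, alternative="two-sided", method=method,
                                   use_continuity=True)
            except ValueError:
                res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                                   use_continuity=True)
            p[t - 1, j] = float(res.pvalue)
            diff = a.mean() - b.mean()
            sign[t - 1, j] = float(np.sign(diff))
    return p, sign


def write_utest_tsv(p: np.ndarray, sign: np.ndarray, path) -> None:
    """Long-format TSV of the discrimination matrix: one row per
    (atom type, attribute) with the p-value and the direction sign."""
    import pandas as pd

    rows = []
    for t in range(p.shape[0]):
        for j in range(p.shape[1]):
            rows.append({"atom_type": t + 1, "attribute": j + 1,
                         "p_value": p[t, j],
                         "sign": {1.0: "+", -1.0: "-", 0.0: "0"}.get(sign[t, j], "0")})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
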