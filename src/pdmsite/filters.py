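"""Interaction-pair filter: a 31x31 matrix gating which atom-type pairs
contribute contact observations to the knowledge base.

A pair (t, j) is admitted when its matrix value is below the threshold
(default -0.1, more negative = more favourable interaction).  When no table
is supplied, an all-admitting matrix (every value -1.0) is used.
"""

from __future__ import annotations

import io
import warnings

import numpy as np

from .atom_types import N_TYPES

__all__ = ["FilterMatrix", "load_filter_matrix", "permissive_filter_matrix"]

DEFAULT_THRESHOLD = -0.1


class FilterMatrix:
    """Symmetric 31x31 value matrix with an admission predicate."""

    def __init__(self, values: np.ndarray, threshold: float = DEFAULT_THRESHOLD):
        values = np.asarray(values, dtype=float)
        if values.shape != (N_TYPES, N_TYPES):
            raise ValueError(f"filter matrix must be {N_TYPES}x{N_TYPES}, got {values.shape}")
        if not np.allclose(values, values.T, equal_nan=True):
            warnings.warn("asymmetric filter matrix; symmetrizing by element-wise minimum")
            values = np.minimum(values, values.T)
        self.values = values
        self.threshold = float(threshold)

    def admits(self, type_a: int, type_b: int) -> bool:
        """True when the pair's value is strictly below the threshold."""
        return bool(self.values[type_a - 1, type_b - 1] < self.threshold)

    def admitted_pairs(self) -> set[tuple[int, int]]:
        ia, ib = np.nonzero(self.values < self.threshold)
        return {(int(a) + 1, int(b) + 1) for a, b in zip(ia, ib)}


def permissive_filter_matrix() -> FilterMatrix:
    """All-admitting default used when no interaction table is available."""
    return FilterMatrix(np.full((N_TYPES, N_TYPES), -1.0))


def load_filter_matrix(table_text: str, threshold: float = DEFAULT_THRESHOLD) -> FilterMatrix:
    """Load a 31x31 numeric TSV (no header) into a FilterMatrix."""
    try:
        values = np.loadtxt(io.StringIO(table_text), delimiter="\t")
    except ValueError as exc:
        raise ValueError(f"filter table is not numeric TSV: {exc}") from exc
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"filter table must be square, got {values.shape}")
    return FilterMatrix(values, threshold=threshold)
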