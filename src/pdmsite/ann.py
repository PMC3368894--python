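"""Feed-forward neural network 32-15-1 trained with resilient
back-propagation (iRprop-).

The loss is the sum of squared errors between the logistic output and the
0/1 class target.  Training is full batch for 1000 iterations; every 10
iterations the model is scored on a validation set by MCC (at threshold
0.5) and the best-scoring snapshot is kept, an early-stopping scheme that
guards against over-fitting without a separate schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import mcc_from_labels

__all__ = ["sigmoid", "AnnModel", "train_ann", "AnnConfig"]

N_INPUT = 32
N_HIDDEN = 15

# iRprop- constants
ETA_PLUS = 1.2
ETA_MINUS = 0.5
DELTA_INIT = 0.1
DELTA_MAX = 50.0
DELTA_MIN = 1e-6


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Logistic function 1/(1+e^-x), stable for large |x|."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class AnnConfig:
    n_iterations: int = 1000
    validate_every: int = 10
    init_scale: float = 0.5       # uniform(-scale, scale) weight init


@dataclass
class AnnModel:
    """Weights of a 32-15-1 network plus its training trace."""

    w1: np.ndarray                 # (32, 15)
    b1: np.ndarray                 # (15,)
    w2: np.ndarray                 # (15, 1)
    b2: np.ndarray                 # (1,)
    best_iteration: int = 0
    best_validation_mcc: float = float("nan")

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Output activity in (0,1) per row of x (n, 32)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.w1.shape[0]:
            raise ValueError(f"expected {self.w1.shape[0]} features, got {x.shape[1]}")
        h = sigmoid(x @ self.w1 + self.b1)
        return sigmoid(h @ self.w2 + self.b2).ravel()

    def params(self) -> dict[str, list]:
        return {k: getattr(self, k).tolist() for k in ("w1", "b1", "w2", "b2")}

    @classmethod
    def from_params(cls, d: dict) -> "AnnModel":
        return cls(**{k: np.asarray(d[k], dtype=float) for k in ("w1", "b1", "w2", "b2")})


def _forward_backward(params, x, y):
    w1, b1, w2, b2 = params
    h = sigmoid(x @ w1 + b1)
    o = sigmoid(h @ w2 + b2)
    err = o - y                                   # (n, 1)
    # SSE loss: dL/do = 2 err; sigmoid' = o(1-o)
    do = 2.0 * err * o * (1.0 - o)
    g_w2 = h.T @ do
    g_b2 = do.sum(axis=0)
    dh = (do @ w2.T) * h * (1.0 - h)
    g_w1 = x.T @ dh
    g_b1 = dh.sum(axis=0)
    return (g_w1, g_b1, g_w2, g_b2)


def train_ann(train_x: np.ndarray, train_y: np.ndarray,
              val_x: np.ndarray, val_y: np.ndarray,
              seed: int = 0, config: AnnConfig | None = None) -> AnnModel:
    """Train by full-batch iRprop-, returning the best-validation snapshot.

    When the validation set holds a single class (MCC undefined) the final
    iteration's weights are returned with a warning.
    """
    import warnings

    config = config or AnnConfig()
    x = np.asarray(train_x, dtype=float)
    y = np.asarray(train_y, dtype=float).reshape(-1, 1)
    vx = np.atleast_2d(np.asarray(val_x, dtype=float))
    vy = np.asarray(val_y, dtype=bool).ravel()
    rng = np.random.default_rng(seed)
    s = config.init_scale
    params = [rng.uniform(-s, s, size=shape) for shape in
              ((N_INPUT, N_HIDDEN), (N_HIDDEN,), (N_HIDDEN, 1), (1,))]
    deltas = [np.full_like(p, DELTA_INIT) for p in params]
    prev_grads = [np.zeros_like(p) for p in params]
    val_degenerate = len(vy) == 0 or vy.all() or not vy.any()
    best: tuple[float, int, list[np.ndarray]] | None = None
    for it in range(1, config.n_iterations + 1):
        grads = _forward_backward(params, x, y)
        for k in range(4):
            g, pg, d = grads[k], prev_grads[k], deltas[k]
            same = g * pg > 0
            flip = g * pg < 0
            d[same] = np.minimum(d[same] * ETA_PLUS, DELTA_MAX)
            d[flip] = np.maximum(d[flip] * ETA_MINUS, DELTA_MIN)
            g = np.where(flip, 0.0, g)           # iRprop-: skip after sign change
            params[k] = params[k] - np.sign(g) * d
            prev_grads[k] = g
        if not val_degenerate and it % config.validate_every == 0:
            model = AnnModel(*params)
            mcc = mcc_from_labels(vy, model.predict(vx) >= 0.5)
            if best is None or mcc > best[0] + 1e-15:
                best = (mcc, it, [p.copy() for p in params])
    if val_degenerate:
        warnings.warn("single-class validation set; returning final iteration")
        return AnnModel(*params, best_iteration=config.n_iterations,
                        best_validation_mcc=float("nan"))
    assert best is not None
    mcc, it, snap = best
    return AnnModel(*snap, best_iteration=it, best_validation_mcc=mcc)
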