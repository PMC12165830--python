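"""Asymmetric loss (ASL) for class-imbalanced classification.

The loss re-weights the cross-entropy terms with focusing exponents that
differ between positive (true-class) and negative (other-class) terms, so
easy negatives contribute little gradient and the minority class is learned
more aggressively. With p = softmax(x) and one-hot labels y, two readings
are implemented:

* ``literal`` — per sample only the true-class term contributes,
  L = -(1 - p_t)^gamma_pos * log p_t. This is the printed per-sample form
  with one-hot labels; note gamma_neg cancels here, so it degenerates to
  focal-style weighting of the positive term (and to plain cross-entropy at
  gamma_pos = 0).
* ``standard`` — per sample, summed over classes,
  L = sum_c -[ y_c (1-p_c)^gamma_pos log p_c
               + (1-y_c) p_c^gamma_neg log(1-p_c) ],
  the asymmetric-loss form in which gamma_neg actively down-weights easy
  negatives. This is the default, with (gamma_pos, gamma_neg) = (0, 4).

Both are averaged over the batch. Probabilities are clamped away from 0/1
by ``prob_floor`` before logs and powers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax as _scipy_log_softmax
from scipy.special import softmax as _scipy_softmax


@dataclass(frozen=True)
class ASLConfig:
    """Focusing exponents and numerical guards for the asymmetric loss."""

    gamma_pos: float = 0.0
    gamma_neg: float = 4.0
    mode: str = "standard"  # or "literal"
    prob_floor: float = 1e-8

    def __post_init__(self) -> None:
        if self.gamma_pos < 0 or self.gamma_neg < 0:
            raise ValueError("gamma exponents must be non-negative")
        if self.mode not in ("standard", "literal"):
            raise ValueError(f"unknown ASL mode {self.mode!r}")
        if not 0 < self.prob_floor <= 0.01:
            raise ValueError("prob_floor must be in (0, 0.01]")


def log_softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable log-softmax along the last axis."""
    x = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite logits")
    return _scipy_log_softmax(x, axis=-1)


def softmax(logits: np.ndarray) -> np.ndarray:
    x = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite logits")
    return _scipy_softmax(x, axis=-1)


def _check_one_hot(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels, dtype=np.float64)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("labels must be an N x C one-hot matrix with C >= 2")
    if not (np.all((y == 0) | (y == 1)) and np.all(y.sum(axis=1) == 1)):
        raise ValueError("label rows must be one-hot")
    return y


def one_hot(indices: np.ndarray, n_classes: int) -> np.ndarray:
    idx = np.asarray(indices, dtype=int)
    out = np.zeros((idx.size, n_classes))
    out[np.arange(idx.size), idx] = 1.0
    return out


def asymmetric_weight(p: np.ndarray, y: np.ndarray, config: ASLConfig) -> np.ndarray:
    """Per-entry asymmetric weight: (1-p)^gamma_pos where y=1, p^gamma_neg where y=0."""
    p = np.clip(np.asarray(p, dtype=np.float64), config.prob_floor, 1 - config.prob_floor)
    y = np.asarray(y, dtype=np.float64)
    return np.where(y == 1, (1 - p) ** config.gamma_pos, p ** config.gamma_neg)


def asl_loss(logits: np.ndarray, labels: np.ndarray, config: ASLConfig = ASLConfig()) -> float:
    """Batch-mean asymmetric loss of raw logits against one-hot labels."""
    y = _check_one_hot(labels)
    x = np.asarray(logits, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"logits shape {x.shape} != labels shape {y.shape}")
    p = np.clip(softmax(x), config.prob_floor, 1 - config.prob_floor)
    if config.mode == "literal":
        p_true = (p * y).sum(axis=1)
        per_sample = -np.log(p_true) * (1 - p_true) ** config.gamma_pos
    else:
        pos = y * (1 - p) ** config.gamma_pos * np.log(p)
        neg = (1 - y) * p ** config.gamma_neg * np.log(1 - p)
        per_sample = -(pos + neg).sum(axis=1)
    return float(per_sample.mean())


def asl_grad(
    logits: np.ndarray, labels: np.ndarray, config: ASLConfig = ASLConfig()
) -> np.ndarray:
    """Analytic d(batch-mean loss)/d(logits), via the softmax Jacobian."""
    y = _check_one_hot(labels)
    x = np.asarray(logits, dtype=np.float64)
    n = x.shape[0]
    p = np.clip(softmax(x), config.prob_floor, 1 - config.prob_floor)
    gp, gn = config.gamma_pos, config.gamma_neg
    # p is clamped into (0, 1), so the gamma-1 powers are finite even at gamma=0
    dpos = gp * (1 - p) ** (gp - 1) * np.log(p) - (1 - p) ** gp / p if gp != 0 else -1.0 / p
    if config.mode == "literal":
        dldp = y * dpos
    else:
        dneg = (
            -gn * p ** (gn - 1) * np.log(1 - p) + p ** gn / (1 - p)
            if gn != 0
            else 1.0 / (1 - p)
        )
        dldp = y * dpos + (1 - y) * dneg
    # chain through softmax: dL/dx_j = p_j (g_j - sum_c g_c p_c)
    inner = (dldp * p).sum(axis=1, keepdims=True)
    return (p * (dldp - inner)) / n


def cross_entropy_config() -> ASLConfig:
    """The gamma-degenerate baseline: literal mode with gamma_pos = 0."""
    return ASLConfig(gamma_pos=0.0, gamma_neg=0.0, mode="literal")
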