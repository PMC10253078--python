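"""Hybrid mean-variance-cross-entropy loss for ordinal age-distribution learning.

Bone age is predicted as a discrete distribution p over K age classes
(class j, j = 1..K, maps to j months). Training combines three terms
computed from one shared softmax pass over the logits z (N x K):

* cross-entropy  Ls = (1/N) sum_i -log p_{i, y_i}   — drives convergence;
* mean loss      Lm = (1/2N) sum_i (m_i - y_i)^2    — an L2 penalty on the
  distribution mean m_i = sum_j j * p_{i,j}, the regression functional used
  at inference;
* variance loss  Lv = (1/N) sum_i v_i, with v_i = sum_j p_{i,j} (j - m_i)^2
  — sharpens the distribution around its mean.

Total: L = Ls + lambda1 * Lm + lambda2 * Lv, defaults lambda1 = 0.001,
lambda2 = 0.0002. The analytic gradient w.r.t. z is provided in closed form
(used both by the trainer and as the object of the finite-difference check):

    dLs/dz_{ik} = (p_{ik} - [k = y_i]) / N
    dLm/dz_{ik} = (m_i - y_i) * p_{ik} (k - m_i) / N
    dLv/dz_{ik} = p_{ik} ((k - m_i)^2 - v_i) / N

All computations use log-sum-exp stabilisation; log-probabilities are floored
at 1e-12 inside the cross-entropy (mean-variance losses are known to
fluctuate early in training, so numerical floors matter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LOG_FLOOR = 1e-12
_NORM_TOL = 1e-6


@dataclass(frozen=True)
class LossWeights:
    """Weights of the mean (lambda1) and variance (lambda2) terms."""

    lambda1: float = 0.001
    lambda2: float = 0.0002

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be >= 0")


def _check_finite(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("logits contain NaN or Inf")
    return z


def _check_labels(y: np.ndarray, k: int) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim != 1:
        raise ValueError("labels must be a 1-D integer vector")
    if np.any(y < 1) or np.any(y > k):
        raise ValueError(f"labels must lie in [1, {k}]")
    return y.astype(int)


def softmax_probs(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max subtraction; accepts a vector or N x K array."""
    z = _check_finite(z)
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def log_softmax(z: np.ndarray) -> np.ndarray:
    z = _check_finite(z)
    shifted = z - z.max(axis=-1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))


def _check_normalized(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    sums = p.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > _NORM_TOL):
        raise ValueError("probability vector does not sum to 1")
    return p


def class_indices(k: int) -> np.ndarray:
    """Class index vector (1, 2, ..., K); class j corresponds to j months."""
    return np.arange(1, k + 1, dtype=float)


def dist_mean(p: np.ndarray) -> np.ndarray | float:
    """Mean of the class distribution, sum_j j * p_j over j = 1..K."""
    p = _check_normalized(p)
    j = class_indices(p.shape[-1])
    m = p @ j
    return float(m) if np.ndim(m) == 0 else m


def dist_var(p: np.ndarray) -> np.ndarray | float:
    """Variance of the class distribution, sum_j p_j (j - m)^2; 0 iff point mass."""
    p = _check_normalized(p)
    j = class_indices(p.shape[-1])
    m = np.expand_dims(p @ j, -1)
    v = (p * (j - m) ** 2).sum(axis=-1)
    return float(v) if np.ndim(v) == 0 else v


def mean_loss(z: np.ndarray, y: np.ndarray) -> float:
    """L2 penalty on the distribution mean: (1/2N) sum_i (m_i - y_i)^2."""
    z = np.atleast_2d(_check_finite(z))
    y = _check_labels(np.atleast_1d(y), z.shape[1])
    p = softmax_probs(z)
    m = p @ class_indices(z.shape[1])
    return float(0.5 * np.mean((m - y) ** 2))


def variance_loss(z: np.ndarray) -> float:
    """Mean distribution variance across the batch: (1/N) sum_i v_i."""
    z = np.atleast_2d(_check_finite(z))
    return float(np.mean(dist_var(softmax_probs(z))))


def cross_entropy_loss(z: np.ndarray, y: np.ndarray) -> float:
    """(1/N) sum_i -log p_{i, y_i}, computed in log space."""
    z = np.atleast_2d(_check_finite(z))
    y = _check_labels(np.atleast_1d(y), z.shape[1])
    logp = np.maximum(log_softmax(z), np.log(LOG_FLOOR))
    return float(-np.mean(logp[np.arange(len(y)), y - 1]))


def hybrid_loss(
    z: np.ndarray, y: np.ndarray, weights: LossWeights = LossWeights()
) -> tuple[float, dict[str, float]]:
    """Total loss Ls + lambda1 * Lm + lambda2 * Lv and its components."""
    ls = cross_entropy_loss(z, y)
    lm = mean_loss(z, y)
    lv = variance_loss(z)
    total = ls + weights.lambda1 * lm + weights.lambda2 * lv
    return total, {"cross_entropy": ls, "mean": lm, "variance": lv, "total": total}


def hybrid_loss_grad(
    z: np.ndarray, y: np.ndarray, weights: LossWeights = LossWeights()
) -> np.ndarray:
    """Closed-form gradient of the total loss w.r.t. the logits z (N x K)."""
    z = np.atleast_2d(_check_finite(z))
    n, k = z.shape
    y = _check_labels(np.atleast_1d(y), k)
    p = softmax_probs(z)
    j = class_indices(k)
    m = p @ j  # (N,)
    dev = j[None, :] - m[:, None]  # (N, K)
    v = (p * dev**2).sum(axis=1)  # (N,)

    grad_ce = p.copy()
    grad_ce[np.arange(n), y - 1] -= 1.0
    grad_mean = (m - y)[:, None] * p * dev
    grad_var = p * (dev**2 - v[:, None])
    total = grad_ce + weights.lambda1 * grad_mean + weights.lambda2 * grad_var
    return total / n


__all__ = [
    "LossWeights",
    "softmax_probs",
    "log_softmax",
    "class_indices",
    "dist_mean",
    "dist_var",
    "mean_loss",
    "variance_loss",
    "cross_entropy_loss",
    "hybrid_loss",
    "hybrid_loss_grad",
]
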