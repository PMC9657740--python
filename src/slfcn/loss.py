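"""Softmax probabilities and the soft-weight softmax loss.

The segmentation loss is an ordinary per-pixel softmax cross-entropy in which
each pixel's contribution is multiplied by its loss weight from the soft-label
weight map; targets remain hard class indices.  Normalisation is the plain
1/M pixel mean by default (``reduction="sum"`` is available; the historical
FCN recipe with its extremely small learning rate pairs with sum reduction,
so the learning rate must be rescaled when switching).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "softmax_probabilities",
    "softmax_loss",
    "soft_weight_softmax_loss",
    "soft_weight_softmax_grad",
    "IGNORE_LABEL",
]

#: Label value excluded from the loss (padded tile borders).
IGNORE_LABEL = 255


def softmax_probabilities(scores: np.ndarray) -> np.ndarray:
    """Per-pixel class probabilities from a (N, H, W) score field.

    Stabilised by subtracting the per-pixel maximum score before
    exponentiation, which leaves the result mathematically unchanged.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise FloatingPointError("non-finite values in score field")
    shifted = scores - scores.max(axis=0, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=0, keepdims=True)


def _target_probs(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape[1:] != labels.shape:
        raise ValueError(
            f"score grid {scores.shape[1:]} does not match labels {labels.shape}"
        )
    p = softmax_probabilities(scores)
    valid = labels != IGNORE_LABEL
    safe = np.where(valid, labels, 0)
    p_t = np.take_along_axis(p, safe[None], axis=0)[0]
    return p, p_t, valid


def softmax_loss(scores: np.ndarray, labels: np.ndarray,
                 reduction: str = "mean") -> float:
    """Cross-entropy: mean (or sum) over pixels of -log p(target class)."""
    _, p_t, valid = _target_probs(scores, labels)
    nll = -np.log(p_t[valid])
    if reduction == "mean":
        return float(nll.sum() / max(valid.sum(), 1))
    if reduction == "sum":
        return float(nll.sum())
    raise ValueError(f"unknown reduction {reduction!r}")


def soft_weight_softmax_loss(scores: np.ndarray, labels: np.ndarray,
                             weights: np.ndarray,
                             reduction: str = "mean") -> float:
    """Weighted cross-entropy: each pixel's -log p scaled by its loss weight.

    Reduces to the unweighted loss for unit weights; linear in the weight map.
    The mean divides by the pixel count M, not by the weight total.
    """
    weights = np.asarray(weights, dtype=np.float64)
    _, p_t, valid = _target_probs(scores, labels)
    if weights.shape != labels.shape:
        raise ValueError("weight map shape does not match labels")
    if np.any(weights <= 0):
        raise ValueError("loss weights must be positive")
    nll = -(weights[valid] * np.log(p_t[valid]))
    if reduction == "mean":
        return float(nll.sum() / max(valid.sum(), 1))
    if reduction == "sum":
        return float(nll.sum())
    raise ValueError(f"unknown reduction {reduction!r}")


def soft_weight_softmax_grad(scores: np.ndarray, labels: np.ndarray,
                             weights: np.ndarray,
                             reduction: str = "mean"):
    """Loss value and gradient w.r.t. the scores.

    d/dz_m^t = w_m * (p_m^t - [t == n_m]) / M  (mean reduction; no /M for sum).
    Ignored pixels contribute zero gradient and are excluded from M.
    """
    weights = np.asarray(weights, dtype=np.float64)
    p, p_t, valid = _target_probs(scores, labels)
    safe = np.where(valid, labels, 0)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, safe[None], 1.0, axis=0)
    grad = weights[None] * (p - onehot)
    grad *= valid[None]
    m = max(int(valid.sum()), 1)
    nll = -(weights[valid] * np.log(p_t[valid]))
    if reduction == "mean":
        return float(nll.sum() / m), grad / m
    if reduction == "sum":
        return float(nll.sum()), grad
    raise ValueError(f"unknown reduction {reduction!r}")
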