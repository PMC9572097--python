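"""Class-weight formulas and weighted categorical cross-entropy.

Two weighting schemes address the severe class imbalance of dermoscopy
archives (in HAM10000 the largest class outnumbers the smallest ~58:1):

* ``class_weights_original`` — inverse class frequency, W_c = N / N_c.
* ``class_weights_balanced`` — the same rescaled by the number of classes,
  W_c = N / (C · N_c), so that the expected weight under the empirical class
  distribution is exactly 1 and the overall loss scale is unchanged.

The weighted categorical cross-entropy is

    L = -(1/N) Σ_n Σ_c W_c · y_nc · log(ŷ_nc)

with one-hot targets y and predicted probabilities ŷ.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "class_weights_original",
    "class_weights_balanced",
    "weighted_cce",
    "weighted_cce_grad",
]

#: predictions are clipped to [CLIP, 1] before the log to avoid -inf
CLIP = 1e-7


def _validate_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.ndim != 1 or counts.size < 1:
        raise ValueError("counts must be a 1-D vector with at least one class")
    if np.any(counts <= 0):
        raise ValueError(f"all class counts must be positive, got {counts}")
    return counts.astype(np.float64)


def class_weights_original(counts) -> np.ndarray:
    """Inverse-frequency weights W_c = N / N_c (the inverse of each class's share)."""
    c = _validate_counts(counts)
    return c.sum() / c


def class_weights_balanced(counts) -> np.ndarray:
    """Balanced weights W_c = N / (C · N_c).

    Equal to ``class_weights_original / C``; satisfies the balance identity
    Σ_c (N_c/N) · W_c = 1, so reweighting does not inflate the loss scale.
    """
    c = _validate_counts(counts)
    return (c.sum() / c) / c.size


def _validate_pred(targets: np.ndarray, predictions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    targets = np.asarray(targets, dtype=np.float64)
    predictions = np.asarray(predictions, dtype=np.float64)
    if targets.shape != predictions.shape or targets.ndim != 2:
        raise ValueError(
            f"targets {targets.shape} and predictions {predictions.shape} must be equal (N,C) shapes"
        )
    if np.any(predictions < 0) or np.any(predictions > 1 + 1e-9):
        raise ValueError("prediction entries must lie in [0, 1]")
    rowsum = predictions.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > 1e-5):
        raise ValueError("each prediction row must sum to 1 within 1e-5")
    return targets, predictions


def weighted_cce(targets, predictions, weights=None) -> float:
    """Weighted categorical cross-entropy over a batch.

    Parameters
    ----------
    targets : (N, C) one-hot matrix of true classes.
    predictions : (N, C) matrix of predicted probabilities (rows sum to 1).
    weights : length-C per-class weights; ``None`` means all ones, which
        reduces to the plain categorical cross-entropy.
    """
    targets, predictions = _validate_pred(targets, predictions)
    n, c = targets.shape
    if weights is None:
        weights = np.ones(c)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (c,):
        raise ValueError(f"weights must have shape ({c},), got {weights.shape}")
    p = np.clip(predictions, CLIP, 1.0)
    return float(-(targets * np.log(p) * weights).sum() / n)


def weighted_cce_grad(targets, predictions, weights=None) -> np.ndarray:
    """Gradient of :func:`weighted_cce` with respect to ``predictions``."""
    targets, predictions = _validate_pred(targets, predictions)
    n, c = targets.shape
    if weights is None:
        weights = np.ones(c)
    weights = np.asarray(weights, dtype=np.float64)
    p = np.clip(predictions, CLIP, 1.0)
    grad = -(targets * weights) / p / n
    grad[(predictions < CLIP) | (predictions > 1.0)] = 0.0  # clipped region is flat
    return grad
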