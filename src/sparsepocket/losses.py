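"""Class-imbalance-aware segmentation losses and ranking metrics.

Binding atoms are a small minority (typically a few percent of a structure),
so plain cross-entropy is dominated by the easy negatives.  The Dice loss
optimizes soft overlap directly; the focal loss re-weights cross-entropy by
(1-p_t)^γ and a class weight α so hard minority examples dominate the
gradient.  Both are exposed as pure functions of probabilities (the public
metric contract) and as logit-space functions with analytic gradients used
by the training loop.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import average_precision_score

__all__ = ["dice_loss", "focal_loss", "prc_auc", "f1_at_threshold"]

_EPS = 1e-12


def _check_aligned(probs: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    probs = np.asarray(probs, dtype=float).reshape(-1)
    labels = np.asarray(labels, dtype=float).reshape(-1)
    if probs.shape != labels.shape:
        raise ValueError(f"length mismatch: {probs.shape} vs {labels.shape}")
    return probs, labels


def dice_loss(probs, labels, smooth: float = 1.0) -> float:
    """1 − (2 Σ p·l + s) / (Σ p + Σ l + s); symmetric in (probs, labels)."""
    probs, labels = _check_aligned(probs, labels)
    num = 2.0 * float(probs @ labels) + smooth
    den = float(probs.sum() + labels.sum()) + smooth
    return 1.0 - num / den


def focal_loss(probs, labels, gamma: float = 1.0, alpha: float = 0.15) -> float:
    """Mean of −α_t (1−p_t)^γ log p_t with p_t = p (label 1) or 1−p (label 0)."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    probs, labels = _check_aligned(probs, labels)
    p = np.clip(probs, _EPS, 1.0 - _EPS)
    pt = np.where(labels == 1, p, 1.0 - p)
    at = np.where(labels == 1, alpha, 1.0 - alpha)
    return float(np.mean(-at * (1.0 - pt) ** gamma * np.log(pt)))


def prc_auc(probs, labels) -> float:
    """Area under the precision–recall curve (step-wise integration)."""
    probs, labels = _check_aligned(probs, labels)
    if labels.sum() == 0:
        raise ValueError("PRC-AUC is undefined without positive labels")
    return float(average_precision_score(labels, probs))


def f1_at_threshold(probs, labels, threshold: float = 0.5) -> float:
    probs, labels = _check_aligned(probs, labels)
    pred = probs >= threshold
    tp = float(np.sum(pred & (labels == 1)))
    fp = float(np.sum(pred & (labels == 0)))
    fn = float(np.sum(~pred & (labels == 1)))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# logit-space losses with gradients (training internals)
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def focal_loss_with_grad(
    logits: np.ndarray, labels: np.ndarray, gamma: float, alpha: float
) -> tuple[float, np.ndarray]:
    """(loss, d loss / d logits) for the focal loss, mean reduction."""
    z = np.asarray(logits, dtype=float).reshape(-1)
    y = np.asarray(labels, dtype=float).reshape(-1)
    n = len(z)
    p = _sigmoid(z)
    p = np.clip(p, _EPS, 1.0 - _EPS)
    pt = np.where(y == 1, p, 1.0 - p)
    at = np.where(y == 1, alpha, 1.0 - alpha)
    one_minus = 1.0 - pt
    loss = float(np.mean(-at * one_minus**gamma * np.log(pt)))
    # dL/dpt, with the γ·(1−pt)^(γ−1)·log(pt) term written stably as
    # γ·(1−pt)^γ · log(pt)/(1−pt)  (log(pt)/(1−pt) → −1 as pt → 1)
    log_ratio = np.where(one_minus > _EPS, np.log(pt) / np.maximum(one_minus, _EPS), -1.0)
    dl_dpt = at * (gamma * one_minus**gamma * log_ratio - one_minus**gamma / pt)
    sign = np.where(y == 1, 1.0, -1.0)
    dpt_dz = sign * pt * one_minus
    return loss, dl_dpt * dpt_dz / n


def dice_loss_with_grad(
    logits: np.ndarray, labels: np.ndarray, smooth: float = 1.0
) -> tuple[float, np.ndarray]:
    """(loss, d loss / d logits) for the soft Dice loss."""
    z = np.asarray(logits, dtype=float).reshape(-1)
    y = np.asarray(labels, dtype=float).reshape(-1)
    p = _sigmoid(z)
    num = 2.0 * float(p @ y) + smooth
    den = float(p.sum() + y.sum()) + smooth
    loss = 1.0 - num / den
    dl_dp = -(2.0 * y * den - num) / den**2
    return loss, dl_dp * p * (1.0 - p)
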