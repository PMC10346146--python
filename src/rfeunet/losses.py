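"""Compound training loss: weighted soft dice + pixelwise cross-entropy.

Two surfaces are provided: plain-NumPy functions that operate on
probabilities / logits and integer label maps (the evaluation-facing API),
and a graph version (:func:`mixed_loss_graph`) that builds the same quantity
as an autodiff :class:`~rfeunet.nn.Tensor` for training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "LossWeights",
    "softmax_np",
    "cross_entropy_loss",
    "dice_loss",
    "mixed_loss",
    "mixed_loss_graph",
]

_LOG_CLAMP = 1e-12
_DICE_EPS = 1e-5


@dataclass(frozen=True)
class LossWeights:
    """lambda1 weights the dice term, lambda2 the cross-entropy term."""

    lambda1: float = 0.5
    lambda2: float = 0.5

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")


def softmax_np(logits: np.ndarray, axis: int) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _batched(pred: np.ndarray, labels: np.ndarray):
    """Normalize to (N, K, H, W) probabilities and (N, H, W) labels."""
    pred = np.asarray(pred, dtype=np.float64)
    labels = np.asarray(labels)
    if pred.ndim == 3:
        pred = pred[None]
        labels = labels[None]
    if pred.ndim != 4 or labels.ndim != 3:
        raise ValueError("expected (K, H, W)/(H, W) or (N, K, H, W)/(N, H, W) inputs")
    if pred.shape[0] != labels.shape[0] or pred.shape[2:] != labels.shape[1:]:
        raise ValueError(f"prediction shape {pred.shape} does not match labels {labels.shape}")
    return pred, labels


def _check_probs(probs: np.ndarray) -> None:
    sums = probs.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-4):
        raise ValueError("predictions must be probabilities summing to 1 over the class axis")


def _one_hot(labels: np.ndarray, n_classes: int, dtype=np.float64) -> np.ndarray:
    n, h, w = labels.shape
    oh = np.zeros((n, n_classes, h, w), dtype=dtype)
    nn, hh, ww = np.meshgrid(np.arange(n), np.arange(h), np.arange(w), indexing="ij")
    oh[nn, labels, hh, ww] = 1.0
    return oh


def cross_entropy_loss(pred_probs: np.ndarray, gt_labels: np.ndarray) -> float:
    """Mean over pixels of -sum_x p(x) log q(x) with one-hot ground truth p."""
    probs, labels = _batched(pred_probs, gt_labels)
    _check_probs(probs)
    n, _, h, w = probs.shape
    nn, hh, ww = np.meshgrid(np.arange(n), np.arange(h), np.arange(w), indexing="ij")
    q_true = probs[nn, labels, hh, ww]
    return float(-np.log(np.maximum(q_true, _LOG_CLAMP)).mean())


def dice_loss(pred_probs: np.ndarray, gt_labels: np.ndarray, eps: float = _DICE_EPS) -> float:
    """1 - mean-over-classes soft dice, with the predicted class probability
    against the one-hot ground truth and smoothing eps in numerator and
    denominator.  All classes (background included) enter the mean."""
    probs, labels = _batched(pred_probs, gt_labels)
    if probs.size == 0:
        raise ValueError("empty prediction")
    _check_probs(probs)
    onehot = _one_hot(labels, probs.shape[1])
    inter = (probs * onehot).sum(axis=(0, 2, 3))
    denom = probs.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3))
    dice = (2.0 * inter + eps) / (denom + eps)
    return float(1.0 - dice.mean())


def mixed_loss(pred_logits: np.ndarray, gt_labels: np.ndarray,
               weights: LossWeights = LossWeights()) -> float:
    """lambda1 * dice + lambda2 * cross-entropy on softmaxed logits."""
    logits, labels = _batched(pred_logits, gt_labels)
    probs = softmax_np(logits, axis=1)
    return (weights.lambda1 * dice_loss(probs, labels)
            + weights.lambda2 * cross_entropy_loss(probs, labels))


def mixed_loss_graph(logits: Tensor, gt_labels: np.ndarray,
                     weights: LossWeights = LossWeights(), eps: float = _DICE_EPS) -> Tensor:
    """Autodiff version of :func:`mixed_loss` for (N, K, H, W) logit tensors."""
    n, k, h, w = logits.shape
    labels = np.asarray(gt_labels)
    if labels.ndim == 2:
        labels = labels[None]
    onehot = _one_hot(labels, k, dtype=logits.dtype)

    m = Tensor(logits.data.max(axis=1, keepdims=True))  # detached shift for stability
    z = logits - m
    ez = z.exp()
    se = ez.sum(axis=1, keepdims=True)
    log_probs = z - se.log()
    ce = -(log_probs * onehot).sum() * (1.0 / (n * h * w))

    probs = ez / se
    inter = (probs * onehot).sum(axis=(0, 2, 3))
    denom = probs.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3))
    dice = (inter * 2.0 + eps) / (denom + eps)
    dl = 1.0 - dice.mean()
    return dl * weights.lambda1 + ce * weights.lambda2
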