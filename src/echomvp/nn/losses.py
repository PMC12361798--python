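"""Fused losses with analytic gradients.

Each loss takes a Tensor of logits and a plain numpy target and returns a
scalar Tensor wired into the graph; the softmax/sigmoid is folded into the
backward pass for numerical stability.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, _node

_EPS = 1e-7


def softmax_cross_entropy(
    logits: Tensor, labels: np.ndarray, class_weights: np.ndarray | None = None
) -> Tensor:
    """Weighted cross-entropy over (N, K) or dense (N, K, H, W) logits."""
    x = logits.data
    if x.ndim == 4:
        n, k = x.shape[0], x.shape[1]
        flat = np.moveaxis(x, 1, -1).reshape(-1, k)
        lab = np.asarray(labels).reshape(-1)
    else:
        flat = x
        lab = np.asarray(labels).reshape(-1)
    m, k = flat.shape
    shifted = flat - flat.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1))
    logp = shifted - logz[:, None]
    w = np.ones(k) if class_weights is None else np.asarray(class_weights, dtype=np.float64)
    sample_w = w[lab]
    total_w = sample_w.sum()
    loss = -(sample_w * logp[np.arange(m), lab]).sum() / total_w

    def backward(g):
        p = np.exp(logp)
        p[np.arange(m), lab] -= 1.0
        grad = p * (sample_w / total_w)[:, None] * g
        if x.ndim == 4:
            grad = np.moveaxis(grad.reshape(x.shape[0], x.shape[2], x.shape[3], k), -1, 1)
        logits.accumulate(grad)

    return _node(np.float64(loss), (logits,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from logits; targets in [0, 1]."""
    x = logits.data.astype(np.float64)
    t = np.asarray(targets, dtype=np.float64)
    loss = (np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))).mean()

    def backward(g):
        s = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        logits.accumulate(g * (s - t) / x.size)

    return _node(np.float64(loss), (logits,), backward)


def soft_iou_loss(logits: Tensor, targets: np.ndarray) -> Tensor:
    """1 - soft intersection-over-union of sigmoid(logits) against targets."""
    x = logits.data.astype(np.float64)
    t = np.asarray(targets, dtype=np.float64)
    p = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
    inter = (p * t).sum()
    union = p.sum() + t.sum() - inter
    loss = 1.0 - (inter + _EPS) / (union + _EPS)

    def backward(g):
        dp = -(t * (union + _EPS) - (inter + _EPS) * (1.0 - t)) / (union + _EPS) ** 2
        logits.accumulate(g * dp * p * (1.0 - p))

    return _node(np.float64(loss), (logits,), backward)
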