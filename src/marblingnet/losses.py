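"""Segmentation losses: cross-entropy, Lovász–Softmax, their composite
(CE-LS), and the soft-dice / focal comparison losses.

All public functions operate on a flat pixel batch: ``probs`` is an
(N, C) array of per-pixel class probabilities (rows sum to 1) and
``targets`` an (N,) integer array of class labels in {0..C-1}.  Pixels
from a mini-batch of patches are flattened jointly before the Lovász
sort, which stabilizes the sorted-gradient estimate at small batch
sizes.

The Lovász–Softmax loss is the Lovász extension of the per-class
Jaccard loss evaluated on the class error vector
``m_i = 1 - p_i(c)`` if ``y_i = c`` else ``p_i(c)``: errors are sorted
in decreasing order and dotted with the discrete gradient of the
Jaccard loss over sorted prefix sets.  For hard {0,1} probabilities it
reduces to the per-class Jaccard loss averaged over classes; for soft
probabilities it is the tightest convex surrogate, piecewise-linear in
each probability.  Classes absent from the target are still included
(with ``m_i = p_i(c)``), so the average is always over all C classes.

:func:`loss_on_logits` exposes the same losses as autograd nodes on
(N, C, H, W) score maps for training, with analytic gradients chained
through the softmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, _node

EPS = 1e-12

LOSS_KINDS = ("ce", "ls", "ce_ls", "dice", "focal")


@dataclass
class LossConfig:
    """Loss selection for training.

    kind : one of ``ce``, ``ls``, ``ce_ls``, ``dice``, ``focal``.
    lam : weight of the Lovász–Softmax term in the composite loss
        (1 = direct addition, the best-performing setting).
    focal_gamma : focusing exponent of the focal loss.
    """
    kind: str = "ce_ls"
    lam: float = 1.0
    focal_gamma: float = 2.0

    def __post_init__(self):
        if self.kind not in LOSS_KINDS:
            raise ValueError(f"unknown loss kind {self.kind!r}; choose from {LOSS_KINDS}")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


def _check(probs: np.ndarray, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    probs = np.asarray(probs, dtype=np.float64)
    targets = np.asarray(targets)
    if probs.ndim != 2 or targets.ndim != 1 or probs.shape[0] != targets.shape[0]:
        raise ValueError(f"expected (N,C) probs and (N,) targets, got "
                         f"{probs.shape} and {targets.shape}")
    if probs.shape[0] == 0:
        raise ValueError("empty pixel batch")
    return probs, targets.astype(np.intp)


def cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean negative log-probability of the true class over all pixels."""
    probs, targets = _check(probs, targets)
    p_true = probs[np.arange(len(targets)), targets]
    return float(-np.mean(np.log(np.clip(p_true, EPS, None))))


def lovasz_grad(gt_sorted: np.ndarray) -> np.ndarray:
    """Discrete gradient of the Jaccard loss over sorted prefix sets.

    ``gt_sorted`` is the 0/1 ground-truth indicator permuted by
    decreasing error.  Entry i is the increase of the Jaccard loss when
    pixel i joins the misprediction set.
    """
    gt_sorted = np.asarray(gt_sorted, dtype=np.float64)
    gts = gt_sorted.sum()
    intersection = gts - np.cumsum(gt_sorted)
    union = gts + np.cumsum(1.0 - gt_sorted)
    jaccard = 1.0 - intersection / union
    if len(gt_sorted) > 1:
        jaccard[1:] = jaccard[1:] - jaccard[:-1]
    return jaccard


def _lovasz_terms(probs: np.ndarray, targets: np.ndarray):
    """Per-class (loss, order, signed gradient) triples for Lovász–Softmax."""
    n, c = probs.shape
    out = []
    for cls in range(c):
        fg = (targets == cls).astype(np.float64)
        errors = np.abs(fg - probs[:, cls])
        order = np.argsort(-errors, kind="stable")  # ties by original index
        grad = lovasz_grad(fg[order])
        loss_c = float(np.dot(errors[order], grad))
        out.append((loss_c, order, grad, fg))
    return out


def lovasz_softmax(probs: np.ndarray, targets: np.ndarray) -> float:
    """Lovász extension of the Jaccard loss, averaged over all classes."""
    probs, targets = _check(probs, targets)
    terms = _lovasz_terms(probs, targets)
    return float(np.mean([t[0] for t in terms]))


def ce_ls(probs: np.ndarray, targets: np.ndarray, lam: float = 1.0) -> float:
    """Composite loss: cross-entropy plus ``lam`` times Lovász–Softmax."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    ce = cross_entropy(probs, targets)
    return ce if lam == 0 else ce + lam * lovasz_softmax(probs, targets)


def dice_loss(probs: np.ndarray, targets: np.ndarray, smooth: float = 0.0) -> float:
    """Soft dice on the foreground class: 1 - 2|P∩G| / (|P|+|G|)."""
    probs, targets = _check(probs, targets)
    p = probs[:, 1]
    g = (targets == 1).astype(np.float64)
    num = 2.0 * np.dot(p, g) + smooth
    den = p.sum() + g.sum() + smooth
    if den == 0:
        return 0.0
    return float(1.0 - num / den)


def focal_loss(probs: np.ndarray, targets: np.ndarray, gamma: float = 2.0) -> float:
    """Focal loss: mean of -(1-p_t)^gamma log(p_t); gamma=0 is cross-entropy."""
    probs, targets = _check(probs, targets)
    p_t = np.clip(probs[np.arange(len(targets)), targets], EPS, 1.0)
    return float(np.mean(-((1.0 - p_t) ** gamma) * np.log(p_t)))


def evaluate(probs: np.ndarray, targets: np.ndarray, cfg: LossConfig) -> float:
    """Evaluate the configured loss on a flat probability batch."""
    if cfg.kind == "ce":
        return cross_entropy(probs, targets)
    if cfg.kind == "ls":
        return lovasz_softmax(probs, targets)
    if cfg.kind == "ce_ls":
        return ce_ls(probs, targets, cfg.lam)
    if cfg.kind == "dice":
        return dice_loss(probs, targets)
    return focal_loss(probs, targets, cfg.focal_gamma)


# ---------------------------------------------------------------------------
# autograd interface for training (scores -> scalar loss Tensor)
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _dloss_dprobs(probs: np.ndarray, targets: np.ndarray, cfg: LossConfig,
                  terms=None) -> np.ndarray:
    """Analytic (sub)gradient of the configured loss w.r.t. probabilities."""
    n, c = probs.shape
    idx = np.arange(n)
    g = np.zeros_like(probs)
    if cfg.kind in ("ls", "ce_ls"):
        lam = 1.0 if cfg.kind == "ls" else cfg.lam
        for cls, (_, order, grad, fg) in enumerate(terms if terms is not None
                                                   else _lovasz_terms(probs, targets)):
            sign = np.where(fg > 0, -1.0, 1.0)        # dm/dp per pixel
            gc = np.empty(n)
            gc[order] = grad
            g[:, cls] += lam * sign * gc / c
    if cfg.kind == "dice":
        p = probs[:, 1]
        t1 = (targets == 1).astype(np.float64)
        den = p.sum() + t1.sum()
        if den > 0:
            num = 2.0 * np.dot(p, t1)
            g[:, 1] = -(2.0 * t1 * den - num) / (den * den)
    if cfg.kind == "focal":
        p_t = np.clip(probs[idx, targets], EPS, 1.0)
        one_m = 1.0 - p_t
        d = -(-cfg.focal_gamma * one_m ** max(cfg.focal_gamma - 1.0, 0.0) * np.log(p_t)
              + one_m ** cfg.focal_gamma / p_t) / n
        # note: derivative of -(1-p)^g log p is g(1-p)^(g-1) log p - (1-p)^g / p
        g[idx, targets] += d
    return g


def loss_on_logits(logits: Tensor, targets: np.ndarray, cfg: LossConfig) -> Tensor:
    """Configured loss as an autograd node on (N, C, H, W) class scores.

    Pixels of the whole mini-batch are flattened jointly.  Gradients are
    analytic: the cross-entropy term back-propagates as (p - y)/N through
    the softmax, every other term as a probability-space (sub)gradient
    chained through the softmax Jacobian.  The Lovász sort is computed
    once and shared between the forward value and the gradient.
    """
    z = logits.data
    n, c, h, w = z.shape
    zf = z.transpose(0, 2, 3, 1).reshape(-1, c).astype(np.float64)
    tf = np.asarray(targets).reshape(-1).astype(np.intp)
    probs = _softmax(zf)
    if cfg.kind in ("ls", "ce_ls"):
        terms = _lovasz_terms(probs, tf)
        ls_val = float(np.mean([t[0] for t in terms]))
        value = ls_val if cfg.kind == "ls" else (
            cross_entropy(probs, tf) + cfg.lam * ls_val)
    else:
        terms = None
        value = evaluate(probs, tf, cfg)
    npix = zf.shape[0]

    def bw(gout):
        scale = float(gout)
        dz = np.zeros_like(zf)
        if cfg.kind in ("ce", "ce_ls"):
            onehot = np.zeros_like(zf)
            onehot[np.arange(npix), tf] = 1.0
            dz += (probs - onehot) / npix
        if cfg.kind != "ce":
            dp = _dloss_dprobs(probs, tf, cfg, terms)
            # softmax Jacobian: dz_k = p_k (dp_k - sum_j p_j dp_j)
            dz += probs * (dp - (probs * dp).sum(axis=1, keepdims=True))
        dz = (scale * dz).reshape(n, h, w, c).transpose(0, 3, 1, 2)
        logits._accumulate(dz.astype(np.float32))

    return _node(np.float32(value), (logits,), bw)
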