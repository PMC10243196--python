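"""Differentiable training losses.

Restoration uses a convex combination of a windowed SSIM loss and the
mean absolute error,

    L = lambda1 * (1 - SSIM(restored, target)) + (1 - lambda1) * |diff|_1,

with lambda1 = 0.84 by default.  The SSIM term is evaluated on the
0-255 scale (where its stabilizers are calibrated) with an 11x11
Gaussian window applied as a valid-region depthwise convolution; the L1
term stays on the model's [-1, 1] scale.

Segmentation uses the Dice loss: one minus the mean per-class Dice
overlap between the predicted probability map and the one-hot labels,
with a small epsilon guarding classes that are empty in both.
"""

from __future__ import annotations

import numpy as np

from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["gaussian_window", "ssim_windowed", "restoration_loss",
           "dice_loss", "one_hot", "DEFAULT_LAMBDA1"]

DEFAULT_LAMBDA1 = 0.84


def gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    """Normalized 2-D Gaussian tap matrix."""
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-0.5 * (ax / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def _coerce(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def ssim_windowed(x: Tensor, y: Tensor, m: float = 2.55, n: float = 7.5,
                  window: int = 11, sigma: float = 1.5) -> Tensor:
    """Mean windowed SSIM between NCHW tensors on the 0-255 scale.

    Local statistics come from a depthwise Gaussian convolution over the
    valid region, so the result is differentiable end to end.
    """
    x, y = _coerce(x), _coerce(y)
    if x.data.shape != y.data.shape:
        raise ValueError("shape mismatch")
    C = x.data.shape[1]
    ax = np.arange(window) - (window - 1) / 2.0
    g1 = np.exp(-0.5 * (ax / sigma) ** 2)
    g1 /= g1.sum()
    # the Gaussian window is separable: two 1-D depthwise passes
    wv = Tensor(np.broadcast_to(g1[None, None, :, None], (C, 1, window, 1)).copy())
    wh = Tensor(np.broadcast_to(g1[None, None, None, :], (C, 1, 1, window)).copy())
    blur = lambda t: F.conv2d(F.conv2d(t, wv, None, padding=0, groups=C),
                              wh, None, padding=0, groups=C)
    ux, uy = blur(x), blur(y)
    vx = blur(x * x) - ux * ux
    vy = blur(y * y) - uy * uy
    cov = blur(x * y) - ux * uy
    c1, c2 = m ** 2, n ** 2
    s = ((ux * uy * 2.0 + c1) * (cov * 2.0 + c2)) \
        / ((ux * ux + uy * uy + c1) * (vx + vy + c2))
    return s.mean()


def restoration_loss(restored: Tensor, target, lambda1: float = DEFAULT_LAMBDA1,
                     m: float = 2.55, n: float = 7.5) -> Tensor:
    """SSIM + L1 composite restoration loss on [-1, 1] images."""
    if not 0.0 <= lambda1 <= 1.0:
        raise ValueError("lambda1 must lie in [0, 1]")
    target = _coerce(target)
    if restored.data.shape != target.data.shape:
        raise ValueError("shape mismatch")
    xs = (restored + 1.0) * 127.5
    ys = (target + 1.0) * 127.5
    ssim_term = 1.0 - ssim_windowed(xs, ys, m=m, n=n)
    l1_term = (restored - target).abs().mean()
    return ssim_term * lambda1 + l1_term * (1.0 - lambda1)


def one_hot(labels: np.ndarray, num_classes: int = 3) -> np.ndarray:
    """HxW (or NxHxW) int labels -> (N,Cls,H,W) one-hot float array."""
    labels = np.asarray(labels)
    if labels.ndim == 2:
        labels = labels[None]
    if labels.min() < 0 or labels.max() >= num_classes:
        raise ValueError(f"labels must lie in [0, {num_classes})")
    eye = np.eye(num_classes, dtype=np.float64)
    return eye[labels].transpose(0, 3, 1, 2)


def dice_loss(probs: Tensor, target_onehot: np.ndarray,
              eps: float = 1e-6) -> Tensor:
    """1 - mean per-class Dice overlap; 0 for a perfect one-hot match.

    probs: (N, Cls, H, W) softmax output; target_onehot: same shape.
    """
    probs = _coerce(probs)
    t = np.asarray(target_onehot, dtype=np.float64)
    if probs.data.shape != t.shape:
        raise ValueError("shape mismatch between probabilities and labels")
    tt = Tensor(t)
    inter = (probs * tt).sum(axis=(0, 2, 3))
    total = probs.sum(axis=(0, 2, 3)) + tt.sum(axis=(0, 2, 3))
    dice = (inter * 2.0 + eps) / (total + eps)
    return 1.0 - dice.mean()
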