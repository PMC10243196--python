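"""Restoration and segmentation quality metrics.

Image metrics (SSIM, PSNR) are computed on the 8-bit 0-255 scale: the
SSIM stabilizers m = 2.55 and n = 7.5 are fractions of that dynamic
range (m = 0.01 * 255), and PSNR's Max is the full range 255.  Model
outputs in [-1, 1] should be passed through :func:`to_uint8_scale`
first.

SSIM follows

    SSIM(x, y) = (2 µx µy + m^2)(2 σxy + n^2)
                 / ((µx^2 + µy^2 + m^2)(σx^2 + σy^2 + n^2))

either from whole-image statistics (``global`` mode) or averaged over an
11x11 Gaussian window (sigma 1.5) map (``windowed`` mode, the reported
metric).

Segmentation metrics come from per-class one-vs-rest confusion counts:
IOU = TP/(TP+FP+FN) per class, mIOU is the unweighted mean over the 3
classes (background included), Recall/Precision are macro means, and F1
is the harmonic mean of those macro values.  A class absent from both
prediction and ground truth counts as 1.0 (vacuously perfect) rather
than poisoning the average with NaNs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

__all__ = ["SSIMParams", "ConfusionCounts", "SegMetrics", "ssim", "psnr",
           "confusion", "seg_metrics", "to_uint8_scale"]

logger = logging.getLogger(__name__)


@dataclass
class SSIMParams:
    m: float = 2.55                 # luminance stabilizer (0.01 * 255)
    n: float = 7.5                  # contrast stabilizer
    mode: str = "windowed"          # "windowed" | "global"
    sigma: float = 1.5              # Gaussian window scale
    truncate: float = 3.5           # -> 11x11 window at sigma 1.5

    def __post_init__(self):
        if self.m <= 0 or self.n <= 0:
            raise ValueError("stabilizers must be positive")
        if self.mode not in ("windowed", "global"):
            raise ValueError("mode must be 'windowed' or 'global'")


def to_uint8_scale(img: np.ndarray) -> np.ndarray:
    """Map model-domain [-1, 1] to the 0-255 metric scale."""
    return (np.asarray(img, dtype=np.float64) + 1.0) * 127.5


def _ssim_channel(x: np.ndarray, y: np.ndarray, p: SSIMParams) -> float:
    c1, c2 = p.m ** 2, p.n ** 2
    if p.mode == "global":
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cov = ((x - mx) * (y - my)).mean()
        return ((2 * mx * my + c1) * (2 * cov + c2)
                / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))
    blur = lambda a: ndi.gaussian_filter(a, p.sigma, truncate=p.truncate)
    ux, uy = blur(x), blur(y)
    vx = blur(x * x) - ux * ux
    vy = blur(y * y) - uy * uy
    cov = blur(x * y) - ux * uy
    s = ((2 * ux * uy + c1) * (2 * cov + c2)
         / ((ux ** 2 + uy ** 2 + c1) * (vx + vy + c2)))
    pad = int(p.truncate * p.sigma + 0.5)   # window radius
    return float(s[pad:-pad, pad:-pad].mean())


def ssim(x: np.ndarray, y: np.ndarray, params: SSIMParams | None = None) -> float:
    """Structural similarity on the 0-255 scale; 1.0 for identical images.

    Multi-channel images are scored per channel and averaged.
    """
    params = params or SSIMParams()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.ndim == 2:
        return float(_ssim_channel(x, y, params))
    return float(np.mean([_ssim_channel(x[..., c], y[..., c], params)
                          for c in range(x.shape[-1])]))


def psnr(restored: np.ndarray, target: np.ndarray, max_val: float = 255.0) -> float:
    """Peak signal-to-noise ratio, dB; +inf for identical images.

    The mean squared error is averaged over all pixels and channels, and
    Max is the dynamic range (255 for 8-bit data), not a per-image max.
    """
    restored = np.asarray(restored, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if restored.shape != target.shape:
        raise ValueError(f"shape mismatch: {restored.shape} vs {target.shape}")
    mse = float(np.mean((restored - target) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_val ** 2 / mse))


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest counts from the Cls x Cls confusion matrix."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    matrix: np.ndarray = field(repr=False, default=None)

    @property
    def num_classes(self) -> int:
        return len(self.tp)


def confusion(pred: np.ndarray, gt: np.ndarray, num_classes: int = 3) -> ConfusionCounts:
    """Tally per-class TP/FP/FN/TN between two label maps."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("label maps must share a shape")
    if pred.min() < 0 or pred.max() >= num_classes \
            or gt.min() < 0 or gt.max() >= num_classes:
        raise ValueError(f"labels must lie in [0, {num_classes})")
    idx = gt.astype(np.int64).ravel() * num_classes + pred.astype(np.int64).ravel()
    mat = np.bincount(idx, minlength=num_classes ** 2).reshape(num_classes,
                                                               num_classes)
    tp = np.diag(mat).astype(np.int64)
    fp = mat.sum(axis=0) - tp      # predicted c but gt differs
    fn = mat.sum(axis=1) - tp      # gt c but predicted differently
    tn = mat.sum() - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, matrix=mat)


@dataclass
class SegMetrics:
    per_class_iou: np.ndarray
    miou: float
    recall: float
    precision: float
    f1: float

    def to_dict(self) -> dict:
        return {"per_class_iou": [float(v) for v in self.per_class_iou],
                "miou": float(self.miou), "recall": float(self.recall),
                "precision": float(self.precision), "f1": float(self.f1)}


def _safe_ratio(num: np.ndarray, den: np.ndarray, other: np.ndarray,
                what: str) -> np.ndarray:
    """num/den per class; a class empty on both sides scores 1.0."""
    out = np.empty(len(num), dtype=np.float64)
    for c in range(len(num)):
        if den[c] > 0:
            out[c] = num[c] / den[c]
        elif other[c] == 0:
            logger.debug("class %d absent from prediction and truth; "
                         "%s treated as 1.0", c, what)
            out[c] = 1.0
        else:
            out[c] = 0.0
    return out


def seg_metrics(pred: np.ndarray, gt: np.ndarray, num_classes: int = 3) -> SegMetrics:
    """IOU per class, mIOU, macro Recall/Precision and the F1 of the
    macro means."""
    cc = confusion(pred, gt, num_classes)
    iou = _safe_ratio(cc.tp, cc.tp + cc.fn + cc.fp,
                      np.zeros_like(cc.tp), "IOU")
    recall = _safe_ratio(cc.tp, cc.tp + cc.fn, cc.fp, "recall")
    precision = _safe_ratio(cc.tp, cc.tp + cc.fp, cc.fn, "precision")
    r, p = float(recall.mean()), float(precision.mean())
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return SegMetrics(per_class_iou=iou, miou=float(iou.mean()),
                      recall=r, precision=p, f1=f1)
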