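"""U-Net semantic segmentation of background / crop / weed.

Canonical 4-stage U-Net: double-conv encoder blocks with 2x2 max pooling,
widths doubling from a configurable base (64 by default), and a decoder
that upsamples bilinearly, halves the channels with a pointwise conv,
concatenates the encoder skip and applies another double conv.  A final
1x1 conv maps to the 3 classes and a per-pixel softmax yields the
probability map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.tensor import Tensor, concat

__all__ = ["SegmenterConfig", "UNet", "predict_labels", "NUM_CLASSES"]

NUM_CLASSES = 3


@dataclass
class SegmenterConfig:
    base_width: int = 64
    num_classes: int = NUM_CLASSES
    stages: int = 4

    def to_dict(self) -> dict:
        return {"base_width": self.base_width, "num_classes": self.num_classes,
                "stages": self.stages}

    @classmethod
    def from_dict(cls, d: dict) -> "SegmenterConfig":
        return cls(**d)


def _double_conv(ci: int, co: int, rng) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(ci, co, 3, padding=1, rng=rng), nn.BatchNorm2d(co), nn.ReLU(),
        nn.Conv2d(co, co, 3, padding=1, rng=rng), nn.BatchNorm2d(co), nn.ReLU())


class UNet(nn.Module):
    def __init__(self, cfg: SegmenterConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg = cfg or SegmenterConfig()
        rng = np.random.default_rng(seed)
        B, S = cfg.base_width, cfg.stages
        widths = [B * 2 ** i for i in range(S + 1)]     # e.g. 64..1024
        self.enc = nn.Sequential(*[
            _double_conv(3 if i == 0 else widths[i - 1], widths[i], rng)
            for i in range(S)])
        self.pool = nn.MaxPool2d()
        self.bottom = _double_conv(widths[S - 1], widths[S], rng)
        self.up = nn.BilinearUpsample2x()
        self.reduce = nn.Sequential(*[
            nn.Conv2d(widths[i + 1], widths[i], 1, rng=rng)
            for i in reversed(range(S))])
        self.dec = nn.Sequential(*[
            _double_conv(2 * widths[i], widths[i], rng)
            for i in reversed(range(S))])
        self.classify = nn.Conv2d(B, cfg.num_classes, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """3-channel image in [-1, 1] -> per-pixel class probabilities."""
        n, c, h, w = x.data.shape
        if c != 3:
            raise ValueError("expected a 3-channel image")
        div = 2 ** self.cfg.stages
        if h % div or w % div:
            raise ValueError(f"spatial dims must be divisible by {div}")
        skips = []
        feat = x
        for block in self.enc:
            feat = block(feat)
            skips.append(feat)
            feat = self.pool(feat)
        feat = self.bottom(feat)
        for i, (red, block) in enumerate(zip(self.reduce, self.dec)):
            feat = red(self.up(feat))
            feat = block(concat([feat, skips[-(i + 1)]], axis=1))
        return self.classify(feat).softmax(axis=1)

    def segment(self, img: np.ndarray) -> np.ndarray:
        """HxWx3 image in [-1, 1] -> HxW label map (no gradients kept)."""
        was_training = self.training
        self.eval()
        try:
            x = Tensor(np.ascontiguousarray(img.transpose(2, 0, 1))[None])
            probs = self.forward(x).data[0]
        finally:
            self.train(was_training)
        return predict_labels(probs.transpose(1, 2, 0))

    def descriptor(self) -> dict:
        return self.cfg.to_dict()


def predict_labels(probs: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over the class axis (last axis of HxWxCls).

    Ties break toward the lowest class index, so the map is deterministic.
    """
    probs = np.asarray(probs)
    if probs.ndim != 3:
        raise ValueError("expected an HxWxCls probability map")
    return probs.argmax(axis=-1).astype(np.uint8)
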