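"""Wide-receptive-field attention network for motion deblurring.

The restorer is an encoder/decoder CNN that predicts a residual
correction to the blurred input and squashes the sum through tanh, so
the model only has to learn the difference between blurred and sharp
images.  Its pieces:

* **Encoder** — a two-conv stem lifts the RGB input to ``C`` channels;
  each level then runs a multi-receptive-field attention block followed
  by a refining conv (whose output is the skip passed to the decoder)
  and a strided 2x2 downsampling conv.  All encoder normalization is
  instance norm: the network trains on small patches at batch size 2,
  where batch statistics are unreliable.
* **Multi-receptive-field attention block** — four parallel chains of
  depthwise-separable conv blocks of depth n = 1..4, so their effective
  receptive fields are (1+2n) = 3, 5, 7 and 9 pixels; the chains are
  concatenated, fused by a pointwise conv, gated by per-pixel attention
  weights, and added to the block input through a learnable per-channel
  skip scale initialized to zero (at init the block is purely its
  attention branch).
* **Decoder** — each level upsamples via a pointwise expansion +
  pixelshuffle, concatenates the encoder skip, fuses with a 3x3 conv
  (batch norm here — the winning normalization placement), and refines
  with a deformable-convolution residual block that resamples features
  at learned sub-pixel offsets, which suits undoing motion displacement.
* **Output head** — three convs taper C -> C/2 -> C/4 -> 3; the final
  layer is zero-initialized so the untrained network is exactly
  ``tanh(input)``.

Inputs and outputs live in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.tensor import Tensor, concat

__all__ = ["RestorerConfig", "DSBlock", "DSGroup", "AttentionGate",
           "WideAttentionBlock", "ConvStem", "RefineBlock", "Downsample",
           "DecoderBlock", "DeformResBlock", "OutputHead", "MotionDeblurNet",
           "expected_parameter_count"]


@dataclass
class RestorerConfig:
    """Architecture hyperparameters of the deblurring network."""

    channels: int = 128
    levels: int = 3
    group_sizes: tuple = (1, 2, 3, 4)
    attention_hidden: int | None = None  # defaults to `channels`
    zero_init_output: bool = True

    def __post_init__(self):
        if self.channels < 4 or self.channels % 4:
            raise ValueError("channels must be >= 4 and divisible by 4")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if not self.group_sizes or any(n < 1 for n in self.group_sizes):
            raise ValueError("group sizes must be a non-empty list of "
                             "positive ints")
        self.group_sizes = tuple(int(n) for n in self.group_sizes)

    @property
    def hidden(self) -> int:
        return self.attention_hidden or self.channels

    def to_dict(self) -> dict:
        return {"channels": self.channels, "levels": self.levels,
                "group_sizes": list(self.group_sizes),
                "attention_hidden": self.attention_hidden,
                "zero_init_output": self.zero_init_output}

    @classmethod
    def from_dict(cls, d: dict) -> "RestorerConfig":
        d = dict(d)
        d["group_sizes"] = tuple(d.get("group_sizes", (1, 2, 3, 4)))
        return cls(**d)


class DSBlock(nn.Module):
    """Depthwise-separable conv block: 1x1 pointwise -> 3x3 depthwise,
    then instance norm and ReLU.

    Both convs are bias-free (the following norm makes biases redundant),
    so the conv parameter cost is C^2 + 9C against 9C^2 for a standard
    3x3 conv.  ``norm=False`` bypasses normalization/activation, which the
    impulse-response tests use to measure the bare receptive field.
    """

    def __init__(self, channels: int, rng=None, norm: bool = True):
        super().__init__()
        self.pointwise = nn.Conv2d(channels, channels, 1, bias=False, rng=rng)
        self.depthwise = nn.Conv2d(channels, channels, 3, padding=1,
                                   groups=channels, bias=False, rng=rng)
        self.norm = nn.InstanceNorm2d(channels) if norm else None

    def forward(self, x):
        x = self.depthwise(self.pointwise(x))
        if self.norm is not None:
            x = self.norm(x).relu()
        return x


class DSGroup(nn.Module):
    """n chained depthwise-separable blocks; receptive field (1 + 2n)."""

    def __init__(self, channels: int, n: int, rng=None, norm: bool = True):
        super().__init__()
        if n < 1:
            raise ValueError("group depth must be >= 1")
        self.blocks = nn.Sequential(*[DSBlock(channels, rng=rng, norm=norm)
                                      for _ in range(n)])
        self.n = n

    def forward(self, x):
        return self.blocks(x)


class AttentionGate(nn.Module):
    """Per-pixel, per-channel gate: sigmoid(conv1x1(relu(conv1x1(x))))."""

    def __init__(self, channels: int, hidden: int, rng=None):
        super().__init__()
        self.conv1 = nn.Conv2d(channels, hidden, 1, rng=rng)
        self.conv2 = nn.Conv2d(hidden, channels, 1, rng=rng)

    def forward(self, x):
        w = self.conv2(self.conv1(x).relu()).sigmoid()
        return w * x


class WideAttentionBlock(nn.Module):
    """Multi-receptive-field residual block with attention and a
    zero-initialized learnable skip scale."""

    def __init__(self, cfg: RestorerConfig, rng=None):
        super().__init__()
        C = cfg.channels
        self.groups = nn.Sequential(*[DSGroup(C, n, rng=rng)
                                      for n in cfg.group_sizes])
        self.fuse = nn.Conv2d(C * len(cfg.group_sizes), C, 1, bias=False,
                              rng=rng)
        self.fuse_norm = nn.InstanceNorm2d(C)
        self.gate = AttentionGate(C, cfg.hidden, rng=rng)
        self.alpha = nn.Parameter(np.zeros(C))  # learnable skip scale

    def feature_extract(self, x):
        branches = [g(x) for g in self.groups]
        return self.fuse_norm(self.fuse(concat(branches, axis=1))).relu()

    def forward(self, x):
        fe = self.feature_extract(x)
        att = self.gate(fe)
        C = self.alpha.data.shape[0]
        return att + x * self.alpha.reshape(1, C, 1, 1)


class ConvStem(nn.Module):
    """Two 3x3 convs (3 -> C -> C), each with instance norm + ReLU."""

    def __init__(self, cfg: RestorerConfig, rng=None):
        super().__init__()
        C = cfg.channels
        self.body = nn.Sequential(
            nn.Conv2d(3, C, 3, padding=1, rng=rng), nn.InstanceNorm2d(C),
            nn.ReLU(),
            nn.Conv2d(C, C, 3, padding=1, rng=rng), nn.InstanceNorm2d(C),
            nn.ReLU(),
        )

    def forward(self, x):
        if x.data.shape[1] != 3:
            raise ValueError("stem expects a 3-channel image")
        return self.body(x)


class RefineBlock(nn.Module):
    """3x3 conv + instance norm + ReLU; emits the encoder skip."""

    def __init__(self, channels: int, rng=None):
        super().__init__()
        self.body = nn.Sequential(
            nn.Conv2d(channels, channels, 3, padding=1, rng=rng),
            nn.InstanceNorm2d(channels), nn.ReLU())

    def forward(self, x):
        return self.body(x)


class Downsample(nn.Module):
    """Strided 2x2 conv halving the spatial dimensions."""

    def __init__(self, channels: int, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(channels, channels, 2, stride=2, rng=rng)

    def forward(self, x):
        _, _, h, w = x.data.shape
        if h % 2 or w % 2:
            raise ValueError("downsampling requires even spatial dims")
        return self.conv(x)


class DeformResBlock(nn.Module):
    """conv3x3(relu(deform_conv3x3(x))) + x — no normalization inside."""

    def __init__(self, channels: int, rng=None):
        super().__init__()
        self.deform = nn.DeformConv2d(channels, channels, rng=rng)
        self.conv = nn.Conv2d(channels, channels, 3, padding=1, rng=rng)

    def forward(self, x):
        return self.conv(self.deform(x).relu()) + x


class DecoderBlock(nn.Module):
    """Pixelshuffle upsample, skip aggregation (batch norm), then a
    deformable residual block."""

    def __init__(self, channels: int, rng=None):
        super().__init__()
        C = channels
        self.expand = nn.Conv2d(C, 4 * C, 1, rng=rng)
        self.shuffle = nn.PixelShuffle(2)
        self.aggregate = nn.Conv2d(2 * C, C, 3, padding=1, rng=rng)
        self.agg_norm = nn.BatchNorm2d(C)
        self.resblock = DeformResBlock(C, rng=rng)

    def forward(self, prev, skip):
        up = self.shuffle(self.expand(prev))
        if up.data.shape[2:] != skip.data.shape[2:]:
            raise ValueError("decoder input is not half the skip's size")
        agg = self.agg_norm(self.aggregate(concat([up, skip], axis=1))).relu()
        return self.resblock(agg)


class OutputHead(nn.Module):
    """Three 3x3 convs tapering C -> C/2 -> C/4 -> 3 (no final activation)."""

    def __init__(self, cfg: RestorerConfig, rng=None):
        super().__init__()
        C = cfg.channels
        if C % 4:
            raise ValueError("channels must be divisible by 4")
        self.conv1 = nn.Conv2d(C, C // 2, 3, padding=1, rng=rng)
        self.conv2 = nn.Conv2d(C // 2, C // 4, 3, padding=1, rng=rng)
        self.conv3 = nn.Conv2d(C // 4, 3, 3, padding=1, rng=rng,
                               zero_init=cfg.zero_init_output)

    def forward(self, x):
        return self.conv3(self.conv2(self.conv1(x).relu()).relu())


class MotionDeblurNet(nn.Module):
    """Full restorer: encode, decode with skips, add residual, tanh."""

    def __init__(self, cfg: RestorerConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg = cfg or RestorerConfig()
        rng = np.random.default_rng(seed)
        C = cfg.channels
        self.stem = ConvStem(cfg, rng=rng)
        self.enc_blocks = nn.Sequential(*[WideAttentionBlock(cfg, rng=rng)
                                          for _ in range(cfg.levels)])
        self.enc_refine = nn.Sequential(*[RefineBlock(C, rng=rng)
                                          for _ in range(cfg.levels)])
        self.downs = nn.Sequential(*[Downsample(C, rng=rng)
                                     for _ in range(cfg.levels - 1)])
        self.decoders = nn.Sequential(*[DecoderBlock(C, rng=rng)
                                        for _ in range(cfg.levels - 1)])
        self.head = OutputHead(cfg, rng=rng)

    # -- pieces ---------------------------------------------------------------
    def _check_input(self, x: Tensor):
        n, c, h, w = x.data.shape
        if c != 3:
            raise ValueError("expected a 3-channel image")
        div = 2 ** (self.cfg.levels - 1)
        if h % div or w % div:
            raise ValueError(f"spatial dims must be divisible by {div}")
        if np.abs(x.data).max() > 1.0 + 1e-9:
            raise ValueError("input must be scaled to [-1, 1]")

    def encode(self, x: Tensor) -> list[Tensor]:
        """Run the encoder; returns the per-level skips, finest first.
        The last entry doubles as the bottleneck."""
        feat = self.stem(x)
        skips = []
        for lvl in range(self.cfg.levels):
            feat = self.enc_blocks[lvl](feat)
            feat = self.enc_refine[lvl](feat)
            skips.append(feat)
            if lvl < self.cfg.levels - 1:
                feat = self.downs[lvl](feat)
        return skips

    def decode(self, skips: list[Tensor]) -> Tensor:
        feat = skips[-1]
        for lvl in range(self.cfg.levels - 2, -1, -1):
            feat = self.decoders[lvl](feat, skips[lvl])
        return feat

    def forward(self, x: Tensor) -> Tensor:
        self._check_input(x)
        res = self.head(self.decode(self.encode(x)))
        return (res + x).tanh()

    def restore(self, img: np.ndarray) -> np.ndarray:
        """Deblur one HxWx3 image in [-1, 1]; inference only — runs in
        eval mode and keeps no gradients, so the weights and norm
        statistics are untouched."""
        was_training = self.training
        self.eval()
        try:
            x = Tensor(np.ascontiguousarray(img.transpose(2, 0, 1))[None])
            out = self.forward(x)
        finally:
            self.train(was_training)
        return out.data[0].transpose(1, 2, 0)

    def descriptor(self) -> dict:
        return self.cfg.to_dict()


def expected_parameter_count(cfg: RestorerConfig) -> int:
    """Closed-form parameter count of :class:`MotionDeblurNet`.

    Derived block by block from the layer shapes; the test suite asserts
    it equals the counted model for a range of configurations.
    """
    C, L, h = cfg.channels, cfg.levels, cfg.hidden
    stem = (27 * C + C + 2 * C) + (9 * C * C + C + 2 * C)
    dsblock = C * C + 9 * C + 2 * C            # pointwise + depthwise + IN
    wab = (sum(n * dsblock for n in cfg.group_sizes)
           + len(cfg.group_sizes) * C * C      # fusion 1x1, no bias
           + 2 * C                             # fusion IN
           + (C * h + h) + (h * C + C)         # attention gate convs
           + C)                                # skip scale alpha
    refine = 9 * C * C + C + 2 * C
    down = 4 * C * C + C
    deform = (243 * C + 27                     # offset/modulation predictor
              + 9 * C * C + C                  # deformable conv weight+bias
              + 9 * C * C + C)                 # trailing 3x3 conv
    decoder = (C * 4 * C + 4 * C               # pixelshuffle expansion
               + 9 * 2 * C * C + C + 2 * C     # aggregation conv + BN
               + deform)
    head = (9 * C * (C // 2) + C // 2
            + 9 * (C // 2) * (C // 4) + C // 4
            + 9 * (C // 4) * 3 + 3)
    return (stem + L * (wab + refine) + (L - 1) * down
            + (L - 1) * decoder + head)
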