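"""Patch-based restoration and the end-to-end restore -> segment pipeline.

Restoration networks are trained on fixed-size patches, and running them
on a whole high-resolution frame both shifts the feature statistics and
costs memory, so inference tiles the image into overlapping patches,
restores each and recomposes.  Overlapping tile predictions are blended
by uniform averaging, which suppresses seam artifacts; when every tile
is a crop of the same image the stitched result reproduces that image
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import SegMetrics, seg_metrics
from .restorer import MotionDeblurNet
from .segmenter import UNet
from .synth import LABEL_PALETTE

__all__ = ["TileGrid", "tile_image", "stitch_tiles", "restore_full",
           "run_pipeline", "PipelineResult", "error_visualization"]

# Fig-style error palette: correct pixels keep the class colors
# (black/red/blue); errors are painted by their ground-truth class.
ERROR_COLORS = {
    1: (255, 255, 0),    # crop missed -> yellow
    2: (255, 165, 0),    # weed missed -> orange
    0: (128, 128, 128),  # background mislabeled -> gray
}


@dataclass
class TileGrid:
    """Tiling plan: overlapping patch origins over a reflect-padded canvas."""

    patch: int
    stride: int
    origins: list          # (row, col) tile corners in the padded frame
    padded_shape: tuple    # (H_pad, W_pad)
    out_shape: tuple       # original (H, W)

    @property
    def n_tiles(self) -> int:
        return len(self.origins)


def _axis_origins(size: int, patch: int, stride: int) -> tuple[list, int]:
    """Tile one axis: returns (origins, padded size)."""
    if size <= patch:
        return [0], patch
    n = int(np.ceil((size - patch) / stride))
    padded = patch + n * stride
    return [i * stride for i in range(n + 1)], padded


def tile_image(img: np.ndarray, patch: int = 256, stride: int = 128):
    """Cut an HxWxC (or HxW) image into overlapping patch x patch tiles.

    The image is reflect-padded on the bottom/right so the tile grid
    covers it exactly; every pixel is covered by at least one tile.
    Returns (tiles, TileGrid).
    """
    if stride < 1 or patch < stride:
        raise ValueError("need patch >= stride >= 1")
    h, w = img.shape[:2]
    rows, hp = _axis_origins(h, patch, stride)
    cols, wp = _axis_origins(w, patch, stride)
    if hp < patch or wp < patch:
        raise ValueError("patch larger than padded image")
    pad = [(0, hp - h), (0, wp - w)] + [(0, 0)] * (img.ndim - 2)
    padded = np.pad(img, pad, mode="reflect") if (hp > h or wp > w) else img
    origins = [(r, c) for r in rows for c in cols]
    tiles = [padded[r:r + patch, c:c + patch] for r, c in origins]
    return tiles, TileGrid(patch=patch, stride=stride, origins=origins,
                           padded_shape=(hp, wp), out_shape=(h, w))


def coverage_map(grid: TileGrid) -> np.ndarray:
    """Per-pixel count of covering tiles on the padded canvas."""
    cov = np.zeros(grid.padded_shape)
    for r, c in grid.origins:
        cov[r:r + grid.patch, c:c + grid.patch] += 1
    return cov


def stitch_tiles(tiles: list, grid: TileGrid) -> np.ndarray:
    """Average overlapping tiles back into a full image and crop the pad."""
    if len(tiles) != grid.n_tiles:
        raise ValueError("tile count does not match the grid")
    t0 = np.asarray(tiles[0])
    extra = t0.shape[2:]
    acc = np.zeros(grid.padded_shape + extra)
    for (r, c), tile in zip(grid.origins, tiles):
        tile = np.asarray(tile)
        if tile.shape != (grid.patch, grid.patch) + extra:
            raise ValueError("tile shape inconsistent with the grid")
        acc[r:r + grid.patch, c:c + grid.patch] += tile
    cov = coverage_map(grid)
    acc /= cov.reshape(cov.shape + (1,) * len(extra))
    h, w = grid.out_shape
    return acc[:h, :w]


def restore_full(img: np.ndarray, restorer: MotionDeblurNet,
                 patch: int = 256, stride: int = 128) -> np.ndarray:
    """Deblur an arbitrarily sized [-1, 1] HxWx3 image tile by tile."""
    div = 2 ** (restorer.cfg.levels - 1)
    if patch % div:
        raise ValueError(f"patch must be divisible by {div} for this model")
    tiles, grid = tile_image(img, patch, stride)
    restored = [restorer.restore(t) for t in tiles]
    return stitch_tiles(restored, grid)


@dataclass
class PipelineResult:
    restored: np.ndarray           # [-1, 1] float image
    labels: np.ndarray             # HxW predicted classes
    metrics: SegMetrics | None     # only when ground truth was given
    error_map: np.ndarray          # HxWx3 uint8 visualization


def error_visualization(pred: np.ndarray, gt: np.ndarray | None) -> np.ndarray:
    """Class-colored map with mistakes repainted by their true class."""
    vis = LABEL_PALETTE[np.asarray(pred, dtype=np.intp)].copy()
    if gt is not None:
        wrong = pred != gt
        for cls, color in ERROR_COLORS.items():
            vis[wrong & (gt == cls)] = color
    return vis


def run_pipeline(img: np.ndarray, restorer: MotionDeblurNet, segmenter: UNet,
                 gt: np.ndarray | None = None, patch: int = 256,
                 stride: int = 128) -> PipelineResult:
    """Restore a blurred [-1, 1] image, then segment the restored image.

    The segmenter input is reflect-padded up to the next multiple of its
    downsampling factor and the label map cropped back afterwards.
    """
    restored = restore_full(img, restorer, patch=patch, stride=stride)
    h, w = restored.shape[:2]
    div = 2 ** segmenter.cfg.stages
    hp = int(np.ceil(h / div)) * div
    wp = int(np.ceil(w / div)) * div
    padded = np.pad(restored, ((0, hp - h), (0, wp - w), (0, 0)),
                    mode="reflect") if (hp > h or wp > w) else restored
    labels = segmenter.segment(padded)[:h, :w]
    m = seg_metrics(labels, gt) if gt is not None else None
    return PipelineResult(restored=restored, labels=labels, metrics=m,
                          error_map=error_visualization(labels, gt))
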