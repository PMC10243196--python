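"""Checkpoint and image I/O.

Checkpoints are NumPy ``.npz`` archives of the flat parameter/buffer
state dict plus a JSON sidecar describing the architecture, so a file
is self-describing and can be loaded without knowing the configuration
that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .restorer import MotionDeblurNet, RestorerConfig
from .segmenter import SegmenterConfig, UNet

__all__ = ["save_checkpoint", "load_restorer", "load_segmenter",
           "load_image", "save_image", "load_dataset"]

_MODEL_KINDS = {"restorer": (MotionDeblurNet, RestorerConfig),
                "segmenter": (UNet, SegmenterConfig)}


def save_checkpoint(model, path: str | Path) -> None:
    """Write <path>.npz (weights) and <path>.json (architecture)."""
    path = Path(path)
    kind = "restorer" if isinstance(model, MotionDeblurNet) else "segmenter"
    state = model.state_dict()
    np.savez(path.with_suffix(".npz"), **state)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({"kind": kind, "config": model.descriptor()}, fh, indent=2)


def _load(path: str | Path, expect_kind: str):
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        desc = json.load(fh)
    if desc["kind"] != expect_kind:
        raise ValueError(f"checkpoint is a {desc['kind']}, "
                         f"expected a {expect_kind}")
    model_cls, cfg_cls = _MODEL_KINDS[expect_kind]
    model = model_cls(cfg_cls.from_dict(desc["config"]))
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


def load_restorer(path: str | Path) -> MotionDeblurNet:
    return _load(path, "restorer")


def load_segmenter(path: str | Path) -> UNet:
    return _load(path, "segmenter")


def load_image(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio
    return np.asarray(iio.imread(path))


def save_image(path: str | Path, img: np.ndarray) -> None:
    import imageio.v3 as iio
    iio.imwrite(path, img)


def load_dataset(manifest_dir: str | Path) -> list[dict]:
    """Read a dataset written by ``make_paired_dataset`` back into memory."""
    manifest_dir = Path(manifest_dir)
    with open(manifest_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    out = []
    for rec in manifest["items"]:
        out.append({k: load_image(manifest_dir / rec[k])
                    for k in ("sharp", "blurred", "label")}
                   | {"scene_seed": rec["scene_seed"],
                      "kernel_seed": rec["kernel_seed"]})
    return out
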