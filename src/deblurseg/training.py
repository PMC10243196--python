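"""Two-stage training: restorer first, then the segmenter on restored data.

Stage 1 trains the deblurring network on blurred/sharp patch pairs with
Adam and a cosine-annealed learning rate (1e-4 down to 1e-7 over the
run).  Stage 2 freezes the restorer and trains the U-Net with Dice loss
on whichever input regime the experiment calls for (sharp, blurred, or
restored images).  The five-scheme ablation harness reproduces the
train/test data combinations used to quantify how much restoration
recovers of the segmentation accuracy lost to motion blur:

    scheme 1 - train sharp,    test sharp      (upper bound)
    scheme 2 - train sharp,    test blurred    (blur at test time only)
    scheme 3 - train blurred,  test blurred
    scheme 4 - train sharp,    test restored
    scheme 5 - train restored, test restored   (the deployed regime)

Every run is deterministic given its seed: model init, batch order and
crop positions all derive from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .losses import dice_loss, one_hot, restoration_loss, DEFAULT_LAMBDA1
from .metrics import SegMetrics, psnr, seg_metrics, ssim, to_uint8_scale
from .nn.optim import Adam, cosine_lr
from .nn.tensor import Tensor
from .restorer import MotionDeblurNet, RestorerConfig
from .segmenter import UNet, SegmenterConfig

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "cosine_lr", "random_crop_pair", "split_pairs",
           "img_to_model", "model_to_img", "RestorationTrainer",
           "SegmentationTrainer", "RestorationResult", "SegmentationResult",
           "run_scheme", "evaluate_restorer", "SCHEMES"]

# (training input, evaluation input) per scheme id
SCHEMES = {
    1: ("sharp", "sharp"),
    2: ("sharp", "blurred"),
    3: ("blurred", "blurred"),
    4: ("sharp", "restored"),
    5: ("restored", "restored"),
}


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults are the full-scale recipe)."""

    lr0: float = 1e-4
    lr_min: float = 1e-7
    batch: int = 2
    epochs: int = 450
    patch: int = 256
    betas: tuple = (0.9, 0.999)
    lambda1: float = DEFAULT_LAMBDA1
    seg_lr: float = 1e-5
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.lr_min > self.lr0:
            raise ValueError("lr_min must not exceed lr0")
        if self.patch < 1 or self.batch < 1 or self.epochs < 1:
            raise ValueError("patch, batch and epochs must be positive")


def img_to_model(img: np.ndarray) -> np.ndarray:
    """uint8 HxWx3 -> float64 in [-1, 1]."""
    return np.asarray(img, dtype=np.float64) / 127.5 - 1.0


def model_to_img(arr: np.ndarray) -> np.ndarray:
    """[-1, 1] float -> uint8 0-255."""
    return np.clip((np.asarray(arr) + 1.0) * 127.5, 0, 255).round().astype(np.uint8)


def random_crop_pair(sharp: np.ndarray, blurred: np.ndarray,
                     label: np.ndarray | None, size: int,
                     rng: np.random.Generator):
    """Cut one shared random window from aligned images.

    Returns (sharp_crop, blurred_crop, label_crop_or_None, (oy, ox)).
    """
    h, w = sharp.shape[:2]
    if blurred.shape[:2] != (h, w) or (label is not None
                                       and label.shape[:2] != (h, w)):
        raise ValueError("images in a pair must share spatial dims")
    if size > h or size > w:
        raise ValueError(f"crop size {size} exceeds image {h}x{w}")
    oy = int(rng.integers(0, h - size + 1))
    ox = int(rng.integers(0, w - size + 1))
    sl = (slice(oy, oy + size), slice(ox, ox + size))
    return (sharp[sl], blurred[sl],
            None if label is None else label[sl], (oy, ox))


def split_pairs(pairs: list, val_fraction: float, seed: int):
    """Deterministic train/validation split of a dataset list."""
    n = len(pairs)
    n_val = int(round(n * val_fraction))
    order = np.random.default_rng(seed).permutation(n)
    val_idx = set(order[:n_val].tolist())
    train = [pairs[i] for i in range(n) if i not in val_idx]
    val = [pairs[i] for i in range(n) if i in val_idx]
    return train, val


def _batch_tensor(images: list[np.ndarray]) -> Tensor:
    arr = np.stack([img_to_model(im).transpose(2, 0, 1) for im in images])
    return Tensor(np.ascontiguousarray(arr))


class _Result:
    """Shared surface of the fitted-trainer result objects."""

    kind = "training"

    def __init__(self, model, history, config):
        self.model = model
        self.history = history
        self.config = config

    @property
    def final_loss(self) -> float:
        return self.history[-1]["train_loss"]

    def summary(self) -> str:
        lines = [f"{self.kind} run: {len(self.history)} epochs, "
                 f"{self.model.count_parameters()} parameters",
                 f"{'epoch':>6} {'train_loss':>12} {'val_loss':>12} {'lr':>12}"]
        for h in self.history:
            val = f"{h['val_loss']:12.6f}" if h["val_loss"] is not None else "           -"
            lines.append(f"{h['epoch']:6d} {h['train_loss']:12.6f} {val} "
                         f"{h['lr']:12.3e}")
        return "\n".join(lines)


class RestorationResult(_Result):
    kind = "restoration"


class SegmentationResult(_Result):
    kind = "segmentation"


class RestorationTrainer:
    """Fits the deblurring network on blurred/sharp pairs."""

    def __init__(self, model_cfg: RestorerConfig | None = None,
                 train_cfg: TrainConfig | None = None):
        self.model_cfg = model_cfg or RestorerConfig()
        self.train_cfg = train_cfg or TrainConfig()

    def fit(self, pairs: list[dict], epochs: int | None = None,
            steps_per_epoch: int | None = None) -> RestorationResult:
        """``pairs``: dicts with uint8 ``sharp``/``blurred`` images."""
        if not pairs:
            raise ValueError("empty dataset")
        cfg = self.train_cfg
        epochs = epochs or cfg.epochs
        train, val = split_pairs(pairs, cfg.val_fraction, cfg.seed)
        if not train:
            train, val = pairs, []
        steps = steps_per_epoch or max(1, int(np.ceil(len(train) / cfg.batch)))
        total = epochs * steps
        model = MotionDeblurNet(self.model_cfg, seed=cfg.seed)
        opt = Adam(model.parameters(), lr=cfg.lr0, betas=cfg.betas)
        rng = np.random.default_rng(cfg.seed + 1)
        patch = min(cfg.patch, min(p["sharp"].shape[0] for p in pairs),
                    min(p["sharp"].shape[1] for p in pairs))
        history = []
        step_idx = 0
        for epoch in range(epochs):
            model.train()
            losses = []
            for _ in range(steps):
                opt.lr = cosine_lr(step_idx, total, cfg.lr0, cfg.lr_min)
                picks = rng.integers(0, len(train), size=cfg.batch)
                sharps, blurs = [], []
                for i in picks:
                    s, b, _, _ = random_crop_pair(train[i]["sharp"],
                                                  train[i]["blurred"],
                                                  None, patch, rng)
                    sharps.append(s)
                    blurs.append(b)
                x = _batch_tensor(blurs)
                y = _batch_tensor(sharps)
                out = model(x)
                loss = restoration_loss(out, y, lambda1=cfg.lambda1)
                if not np.isfinite(loss.item()):
                    raise FloatingPointError(
                        f"non-finite restoration loss at step {step_idx}")
                model.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
                step_idx += 1
            val_loss = None
            if val:
                model.eval()
                vals = []
                for p in val:
                    x = _batch_tensor([p["blurred"]])
                    y = _batch_tensor([p["sharp"]])
                    vals.append(restoration_loss(model(x), y,
                                                 lambda1=cfg.lambda1).item())
                val_loss = float(np.mean(vals))
            history.append({"epoch": epoch + 1,
                            "train_loss": float(np.mean(losses)),
                            "val_loss": val_loss, "lr": opt.lr})
            logger.info("restorer epoch %d/%d: train %.5f val %s lr %.2e",
                        epoch + 1, epochs, history[-1]["train_loss"],
                        f"{val_loss:.5f}" if val_loss is not None else "-",
                        opt.lr)
        return RestorationResult(model, history, self)


def _restore_images(restorer: MotionDeblurNet, images: list[np.ndarray]):
    """Deblur via the deployment path: patch-based tiled inference, so the
    network sees the patch statistics it was trained on."""
    from .inference import restore_full

    out = []
    for im in images:
        patch = min(64, im.shape[0], im.shape[1])
        restored = restore_full(img_to_model(im), restorer,
                                patch=patch, stride=max(1, patch // 2))
        out.append(model_to_img(restored))
    return out


def _segmenter_inputs(pairs: list[dict], mode: str,
                      restorer: MotionDeblurNet | None) -> list[np.ndarray]:
    if mode in ("sharp", "blurred"):
        return [p[mode] for p in pairs]
    if mode == "restored":
        if restorer is None:
            raise ValueError("restored mode requires a fitted restorer")
        return _restore_images(restorer, [p["blurred"] for p in pairs])
    raise ValueError(f"unknown input mode {mode!r}")


class SegmentationTrainer:
    """Fits the U-Net with Dice loss; the restorer (if any) stays frozen.

    ``input_mode`` selects what the segmenter sees: sharp originals,
    blurred images, or blurred images passed through the restorer.
    Restored inputs are produced by inference only — no gradient ever
    reaches the restorer and its weights are untouched.
    """

    def __init__(self, seg_cfg: SegmenterConfig | None = None,
                 train_cfg: TrainConfig | None = None,
                 input_mode: str = "restored",
                 restorer: MotionDeblurNet | None = None):
        if input_mode not in ("sharp", "blurred", "restored"):
            raise ValueError("input_mode must be sharp|blurred|restored")
        self.seg_cfg = seg_cfg or SegmenterConfig()
        self.train_cfg = train_cfg or TrainConfig()
        self.input_mode = input_mode
        self.restorer = restorer

    def fit(self, pairs: list[dict], epochs: int | None = None,
            steps_per_epoch: int | None = None) -> SegmentationResult:
        if not pairs:
            raise ValueError("empty dataset")
        if any("label" not in p or p["label"] is None for p in pairs):
            raise ValueError("segmentation training requires label maps")
        cfg = self.train_cfg
        epochs = epochs or cfg.epochs
        inputs = _segmenter_inputs(pairs, self.input_mode, self.restorer)
        labels = [p["label"] for p in pairs]
        steps = steps_per_epoch or max(1, int(np.ceil(len(pairs) / cfg.batch)))
        model = UNet(self.seg_cfg, seed=cfg.seed)
        opt = Adam(model.parameters(), lr=cfg.seg_lr, betas=cfg.betas)
        rng = np.random.default_rng(cfg.seed + 2)
        div = 2 ** self.seg_cfg.stages
        patch = min(cfg.patch, min(im.shape[0] for im in inputs),
                    min(im.shape[1] for im in inputs))
        patch -= patch % div
        history = []
        ncls = self.seg_cfg.num_classes
        for epoch in range(epochs):
            model.train()
            losses = []
            for _ in range(steps):
                picks = rng.integers(0, len(inputs), size=cfg.batch)
                imgs, labs = [], []
                for i in picks:
                    im, _, lab, _ = random_crop_pair(inputs[i], inputs[i],
                                                     labels[i], patch, rng)
                    imgs.append(im)
                    labs.append(lab)
                x = _batch_tensor(imgs)
                probs = model(x)
                loss = dice_loss(probs, one_hot(np.stack(labs), ncls))
                if not np.isfinite(loss.item()):
                    raise FloatingPointError(
                        f"non-finite Dice loss in epoch {epoch + 1}")
                model.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
            history.append({"epoch": epoch + 1,
                            "train_loss": float(np.mean(losses)),
                            "val_loss": None, "lr": cfg.seg_lr})
            logger.info("segmenter epoch %d/%d (%s inputs): dice %.5f",
                        epoch + 1, epochs, self.input_mode,
                        history[-1]["train_loss"])
        return SegmentationResult(model, history, self)


def evaluate_segmenter(model: UNet, pairs: list[dict], mode: str,
                       restorer: MotionDeblurNet | None = None) -> SegMetrics:
    """Pool pixel-level confusion over a test set and report metrics."""
    inputs = _segmenter_inputs(pairs, mode, restorer)
    preds = np.stack([model.segment(img_to_model(im)) for im in inputs])
    gts = np.stack([p["label"] for p in pairs])
    return seg_metrics(preds, gts)


def run_scheme(scheme_id: int, train_pairs: list[dict], test_pairs: list[dict],
               restorer: MotionDeblurNet | None = None,
               seg_cfg: SegmenterConfig | None = None,
               train_cfg: TrainConfig | None = None,
               epochs: int | None = None,
               steps_per_epoch: int | None = None) -> SegMetrics:
    """Train the segmenter under one blur/restore regime and score it."""
    if scheme_id not in SCHEMES:
        raise ValueError(f"scheme id must be in {sorted(SCHEMES)}")
    train_mode, test_mode = SCHEMES[scheme_id]
    if "restored" in (train_mode, test_mode) and restorer is None:
        raise ValueError(f"scheme {scheme_id} requires a fitted restorer")
    trainer = SegmentationTrainer(seg_cfg, train_cfg, input_mode=train_mode,
                                  restorer=restorer)
    result = trainer.fit(train_pairs, epochs=epochs,
                         steps_per_epoch=steps_per_epoch)
    return evaluate_segmenter(result.model, test_pairs, test_mode, restorer)


def evaluate_restorer(model: MotionDeblurNet, pairs: list[dict],
                      patch: int | None = None,
                      stride: int | None = None) -> dict:
    """Mean PSNR/SSIM of restored and of unrestored blurred images.

    With ``patch`` set, restoration runs through the patch-based tiled
    inference path (matching training patch statistics); otherwise the
    whole frame is restored in one pass.
    """
    from .inference import restore_full

    rows = {"psnr_blurred": [], "psnr_restored": [],
            "ssim_blurred": [], "ssim_restored": []}
    for p in pairs:
        sharp = p["sharp"].astype(np.float64)
        blurred = p["blurred"].astype(np.float64)
        x = img_to_model(p["blurred"])
        if patch is not None:
            restored = to_uint8_scale(
                restore_full(x, model, patch=patch,
                             stride=stride or patch // 2))
        else:
            restored = to_uint8_scale(model.restore(x))
        rows["psnr_blurred"].append(psnr(blurred, sharp))
        rows["psnr_restored"].append(psnr(restored, sharp))
        rows["ssim_blurred"].append(ssim(blurred, sharp))
        rows["ssim_restored"].append(ssim(restored, sharp))
    return {k: float(np.mean(v)) for k, v in rows.items()}
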