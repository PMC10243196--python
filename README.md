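# deblurseg

Motion deblurring and crop/weed semantic segmentation for field images.

Cameras on weeding robots and field rigs produce frames smeared by
vehicle vibration and plant motion.  Motion blur destroys the fine leaf
boundaries that pixel-level crop/weed classification depends on, so
segmentation accuracy collapses exactly when the robot is moving.
`deblurseg` implements a two-stage answer:

1. **Restore** — a wide-receptive-field attention encoder/decoder CNN
   deblurs the frame.  Its encoder blocks fuse four parallel
   depthwise-separable conv chains with receptive fields 3/5/7/9 px, gate
   them with per-pixel attention, and pass the input through a learnable,
   zero-initialized skip scale; its decoder upsamples by pixelshuffle and
   refines with modulated deformable-convolution residual blocks.  The
   network predicts a residual and outputs `tanh(F_res + I_blur)` on
   [-1, 1] images.  Training minimizes
   `0.84 * (1 - SSIM) + 0.16 * L1` with Adam under cosine annealing
   (1e-4 -> 1e-7).
2. **Segment** — a classic U-Net (4 stages, base width 64, softmax over
   background/crop/weed) trained with Dice loss on images the frozen
   restorer has deblurred, so train- and test-time statistics match.

Everything runs on a self-contained NumPy stack: the package ships its
own reverse-mode autodiff, conv/deformable-conv/pooling primitives and
Adam (`deblurseg.nn`), a synthetic data generator for camera-shake blur
kernels and labeled plant scenes (`deblurseg.synth`), patch-based tiled
inference for arbitrarily large frames, and metrics (windowed SSIM with
stabilizers m=2.55, n=7.5; PSNR; per-class IOU / mIOU / macro
precision-recall / F1).

## Worked example

```python
import numpy as np
from deblurseg import (BlurParams, RestorerConfig, RestorationTrainer,
                       SceneSpec, TrainConfig, evaluate_restorer,
                       generate_pairs)

scene = SceneSpec(height=96, width=96, n_crops=2, n_weeds=3,
                  crop_radius=(7, 11), weed_radius=(3, 5))
blur = BlurParams(kernel_size=11, inertia=0.3)
train_pairs = generate_pairs(8, scene, blur, seed=100)
test_pairs = generate_pairs(6, scene, blur, seed=200)

trainer = RestorationTrainer(
    RestorerConfig(channels=8, levels=2),
    TrainConfig(patch=64, batch=4, lr0=2e-3, lr_min=2e-5,
                val_fraction=0.0, seed=0))
result = trainer.fit(train_pairs, epochs=10, steps_per_epoch=20)
print(f"loss {result.history[0]['train_loss']:.3f} -> "
      f"{result.final_loss:.3f}")
print({k: round(v, 2) for k, v in
       evaluate_restorer(result.model, test_pairs,
                         patch=64, stride=32).items()})
```

prints (deterministic given the seeds):

```
loss 0.146 -> 0.130
{'psnr_blurred': 32.52, 'psnr_restored': 32.57, 'ssim_blurred': 0.82, 'ssim_restored': 0.83}
```

The held-out PSNR and SSIM of the restored images edge past the blurred
baseline after only 200 optimizer steps — a miniature of the full
recipe, whose gains grow with scale.  `evaluate_restorer` measures
restoration through the same patch-based tiled inference used in
deployment, so the network sees the patch statistics it was trained on.

The full-scale configuration is `RestorerConfig()` (C=128, 3 levels,
~3.0M parameters) with `TrainConfig()` (256-px patches, batch 2, 450
epochs, lr 1e-4 -> 1e-7).

A command-line interface covers the whole workflow:

```bash
deblurseg synth --n 16 --height 256 --width 256 --seed 0 --out data/
deblurseg train-restorer --data data/ --out ckpt/restorer
deblurseg train-segmenter --data data/ --restorer ckpt/restorer --out ckpt/unet
deblurseg restore --in blurred.png --out restored.png --ckpt ckpt/restorer
deblurseg segment --in blurred.png --out labels.png \
    --restorer ckpt/restorer --segmenter ckpt/unet --gt gt.png --report report.json
```

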