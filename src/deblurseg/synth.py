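"""Synthetic camera-shake blur and crop/weed field scenes.

Real field images of row crops come with two kinds of ground truth this
package needs: a sharp counterpart for each motion-blurred frame, and a
per-pixel background/crop/weed label map.  This module manufactures both
so the full restore-then-segment pipeline can be built and exercised
without external downloads.

Motion blur is modeled as convolution with a point-spread function (PSF)
traced by a nonlinear camera-shake trajectory: a 2-D random walk with
momentum (velocity decays by an inertia factor and receives Gaussian
impulses), rasterized onto a kernel canvas with bilinear splatting and
normalized to unit mass.

Field scenes are green plant blobs on textured soil: crops are larger
rosettes of overlapping ellipses, weeds are smaller hue-shifted blobs.
The label map is exact by construction because classes are painted at
the same time as the pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "Trajectory", "BlurParams", "SceneSpec",
    "generate_trajectory", "rasterize_kernel", "apply_blur",
    "generate_field_scene", "generate_pairs", "make_paired_dataset",
    "LABEL_PALETTE", "label_to_rgb",
]

# visualization palette: background black, crop red, weed blue
LABEL_PALETTE = np.array([[0, 0, 0], [255, 0, 0], [0, 0, 255]], dtype=np.uint8)


@dataclass
class Trajectory:
    """An ordered sequence of continuous 2-D displacements (pixels)."""

    points: np.ndarray  # (n_steps, 2) float, centered

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.shape[0] < 1 or self.points.shape[1] != 2:
            raise ValueError("trajectory needs at least one 2-D point")

    @property
    def n_steps(self) -> int:
        return self.points.shape[0]


@dataclass
class BlurParams:
    """Knobs of the synthetic camera-shake model."""

    n_steps: int = 64
    inertia: float = 0.7
    impulse_scale: float = 1.0
    kernel_size: int = 33


@dataclass
class SceneSpec:
    """Layout of a synthetic crop/weed field scene."""

    height: int = 256
    width: int = 256
    n_crops: int = 3
    n_weeds: int = 5
    crop_radius: tuple = (14, 24)      # semi-axis range of crop leaves, px
    weed_radius: tuple = (5, 10)       # semi-axis range of weed blobs, px
    crop_hue: tuple = (0.26, 0.36)     # HSV hue range (green)
    weed_hue: tuple = (0.16, 0.24)     # HSV hue range (yellow-green)
    sat_range: tuple = (0.3, 0.5)      # plant saturation (diffuse daylight)
    val_range: tuple = (0.52, 0.7)     # plant brightness
    soil_base: tuple = (128, 112, 96)  # mean soil RGB
    soil_noise: float = 10.0           # soil texture amplitude (grey levels)
    soil_smooth: float = 2.0           # gaussian sigma of the texture, px
    margin: float = 4.0                # min gap between objects, px
    max_attempts: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.height < 64 or self.width < 64:
            raise ValueError("scene dimensions must be at least 64 pixels")
        if self.n_crops < 0 or self.n_weeds < 0:
            raise ValueError("object counts must be nonnegative")

    @classmethod
    def scaled(cls, height: int, width: int, **kwargs) -> "SceneSpec":
        """Spec with object sizes scaled from the 256-px reference layout,
        so small canvases still hold the default plant counts."""
        s = min(height, width) / 256.0
        base = cls()
        kwargs.setdefault("crop_radius",
                          tuple(max(3, round(r * s)) for r in base.crop_radius))
        kwargs.setdefault("weed_radius",
                          tuple(max(2, round(r * s)) for r in base.weed_radius))
        return cls(height=height, width=width, **kwargs)


def generate_trajectory(n_steps: int, inertia: float = 0.7,
                        impulse_scale: float = 1.0, seed: int = 0) -> Trajectory:
    """Random-walk-with-momentum shake path.

    Velocity update v_{t+1} = inertia * v_t + Gaussian impulse; positions
    are the cumulative sums of the velocities, recentred on the origin.
    Deterministic given ``seed``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not 0.0 <= inertia <= 1.0:
        raise ValueError("inertia must lie in [0, 1]")
    if impulse_scale <= 0:
        raise ValueError("impulse_scale must be positive")
    if n_steps == 1:
        return Trajectory(np.zeros((1, 2)))
    rng = np.random.default_rng(seed)
    v = np.zeros(2)
    vel = np.empty((n_steps - 1, 2))
    for t in range(n_steps - 1):
        v = inertia * v + rng.normal(0.0, impulse_scale, size=2)
        vel[t] = v
    pos = np.vstack([np.zeros((1, 2)), np.cumsum(vel, axis=0)])
    pos -= pos.mean(axis=0)
    return Trajectory(pos)


def rasterize_kernel(traj: Trajectory, K: int = 33) -> np.ndarray:
    """Splat a trajectory onto a K x K canvas as a unit-mass PSF.

    Points are auto-rescaled (never clipped) to fit the canvas, then each
    sub-pixel point is distributed over its four neighboring cells with
    bilinear weights; the result is normalized to sum to 1.
    """
    if K < 1 or K % 2 == 0:
        raise ValueError("kernel size must be odd and positive")
    pts = traj.points.copy()
    half = (K - 1) / 2.0
    limit = half - 0.5 if K > 1 else 0.0
    extent = np.abs(pts).max()
    if extent > limit:
        pts = pts * (limit / extent) if limit > 0 else pts * 0.0
    c = half
    # splat on a one-cell-padded canvas: the +1 neighbors of points on the
    # last row/column carry zero weight but must be addressable
    canvas = np.zeros((K + 1, K + 1))
    ys = pts[:, 0] + c
    xs = pts[:, 1] + c
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    fy = ys - y0
    fx = xs - x0
    for dy, wy in ((0, 1 - fy), (1, fy)):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            np.add.at(canvas, (y0 + dy, x0 + dx), wy * wx)
    kernel = canvas[:K, :K]
    total = kernel.sum()
    if total <= 0:  # pragma: no cover - cannot happen for valid trajectories
        raise RuntimeError("empty kernel after rasterization")
    return kernel / total


def apply_blur(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve each channel with the PSF using reflect-padded borders.

    Accepts (H, W) or (H, W, 3); preserves shape, dtype float64 out.
    """
    img = np.asarray(img, dtype=np.float64)
    k = np.asarray(kernel, dtype=np.float64)
    if abs(k.sum() - 1.0) > 1e-6:
        raise ValueError("kernel must be normalized to unit sum")
    h, w = img.shape[:2]
    if k.shape[0] > h or k.shape[1] > w:
        raise ValueError("kernel larger than image")
    if img.ndim == 2:
        return ndi.convolve(img, k, mode="reflect")
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        out[..., c] = ndi.convolve(img[..., c], k, mode="reflect")
    return out


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.array(rgb) * 255.0


def _place_objects(rng, spec: SceneSpec, count: int, radius_range: tuple,
                   occupied: list) -> list:
    """Draw non-overlapping object centers; bounded retry then error."""
    placed = []
    # worst-case span of one plant: leaf offset + largest semi-axis
    reach = radius_range[1] + radius_range[0] * 0.6
    if count and 2 * reach >= min(spec.height, spec.width):
        raise RuntimeError("objects are too large for the scene canvas")
    for _ in range(count):
        for _attempt in range(spec.max_attempts):
            cy = rng.uniform(reach, spec.height - reach)
            cx = rng.uniform(reach, spec.width - reach)
            if all(np.hypot(cy - oy, cx - ox) > reach + orad + spec.margin
                   for oy, ox, orad in occupied):
                occupied.append((cy, cx, reach))
                placed.append((cy, cx))
                break
        else:
            raise RuntimeError("could not place object without overlap; "
                               "reduce counts or enlarge the scene")
    return placed


def _paint_plant(img, labels, rng, cy, cx, radius_range, hue_range, cls,
                 n_leaves, sat_range=(0.35, 0.6), val_range=(0.5, 0.72)):
    hue = rng.uniform(*hue_range)
    for leaf in range(n_leaves):
        angle = rng.uniform(0, np.pi)
        a = rng.uniform(*radius_range)
        b = a * rng.uniform(0.35, 0.7)
        off = 0.0 if leaf == 0 else rng.uniform(0, radius_range[0] * 0.6)
        theta = rng.uniform(0, 2 * np.pi)
        ey = cy + off * np.sin(theta)
        ex = cx + off * np.cos(theta)
        rr, cc = draw_ellipse(ey, ex, a, b, shape=img.shape[:2],
                              rotation=angle)
        val = _hsv_to_rgb(hue + rng.uniform(-0.02, 0.02),
                          rng.uniform(*sat_range), rng.uniform(*val_range))
        img[rr, cc] = val + rng.normal(0, 6.0, size=(rr.size, 3))
        labels[rr, cc] = cls


def generate_field_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a soil/crop/weed scene and its exact label map.

    Returns (image uint8 HxWx3, labels uint8 HxW with 0=background,
    1=crop, 2=weed).  Distinct plants never touch, so connected
    components of each class equal the requested object counts.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    noise = rng.normal(0.0, 1.0, size=(h, w, 3))
    noise = ndi.gaussian_filter(noise, sigma=(spec.soil_smooth, spec.soil_smooth, 0))
    noise *= spec.soil_noise / max(noise.std(), 1e-9)
    img = np.array(spec.soil_base, dtype=np.float64) + noise
    labels = np.zeros((h, w), dtype=np.uint8)

    occupied: list = []
    crops = _place_objects(rng, spec, spec.n_crops, spec.crop_radius, occupied)
    weeds = _place_objects(rng, spec, spec.n_weeds, spec.weed_radius, occupied)
    for cy, cx in crops:
        _paint_plant(img, labels, rng, cy, cx, spec.crop_radius,
                     spec.crop_hue, 1, n_leaves=rng.integers(4, 7),
                     sat_range=spec.sat_range, val_range=spec.val_range)
    for cy, cx in weeds:
        _paint_plant(img, labels, rng, cy, cx, spec.weed_radius,
                     spec.weed_hue, 2, n_leaves=rng.integers(1, 3),
                     sat_range=spec.sat_range, val_range=spec.val_range)
    return np.clip(img, 0, 255).astype(np.uint8), labels


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible sub-seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n) % (2 ** 31)


def generate_pairs(n: int, spec: SceneSpec, blur: BlurParams | None = None,
                   seed: int = 0) -> list[dict]:
    """In-memory dataset: n dicts with sharp/blurred/label arrays + seeds."""
    blur = blur or BlurParams()
    seeds = _child_seeds(seed, 2 * n).reshape(-1, 2) if n else np.empty((0, 2), int)
    out = []
    for i in range(n):
        scene_seed, kernel_seed = int(seeds[i, 0]), int(seeds[i, 1])
        sspec = SceneSpec(**{**spec.__dict__, "seed": scene_seed})
        sharp, labels = generate_field_scene(sspec)
        traj = generate_trajectory(blur.n_steps, blur.inertia,
                                   blur.impulse_scale, seed=kernel_seed)
        kernel = rasterize_kernel(traj, blur.kernel_size)
        blurred = np.clip(apply_blur(sharp.astype(np.float64), kernel),
                          0, 255).astype(np.uint8)
        out.append({"sharp": sharp, "blurred": blurred, "label": labels,
                    "scene_seed": scene_seed, "kernel_seed": kernel_seed})
    return out


def make_paired_dataset(n: int, spec: SceneSpec, blur: BlurParams | None = None,
                        out_dir: str | Path = ".", seed: int = 0) -> dict:
    """Write n (sharp, blurred, label) PNG triples plus a JSON manifest.

    The manifest records relative paths and the per-image scene/kernel
    seeds, so a dataset is reproducible byte-for-byte from (spec, seed).
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, item in enumerate(generate_pairs(n, spec, blur, seed)):
        names = {k: f"{k}_{i:04d}.png" for k in ("sharp", "blurred", "label")}
        for k, fname in names.items():
            iio.imwrite(out_dir / fname, item[k])
        records.append({**names, "scene_seed": item["scene_seed"],
                        "kernel_seed": item["kernel_seed"]})
    manifest = {"n": n, "seed": seed, "items": records}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def label_to_rgb(labels: np.ndarray) -> np.ndarray:
    """Map class indices to the black/red/blue display palette."""
    return LABEL_PALETTE[np.asarray(labels, dtype=np.intp)]
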