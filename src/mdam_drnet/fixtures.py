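"""Deterministic synthetic strawberry-leaf images, splits and augmentations.

Seven classes are modelled after the field descriptions of strawberry leaf
conditions: healthy leaves and six diseases whose lesions differ in color and
shape — white round powdery-mildew spots, purplish-red "snake eye" leaf-spot
lesions (gray center, purplish-brown ring), yellow-brown V-shaped Botrytis
cinerea wedges, reddish-brown spindle-shaped anthracnose lesions, long
yellow-brown verticillium-wilt strips, and purple-brown leaf-scorch
shrivelling. The renderer is intentionally parametric and flat (green leaf
blade with veins, analytic spot masks): it exists to exercise the feature
descriptors and the network, not to model botany.

Every generator output is a pure function of (spec, size, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import zlib

import numpy as np
from PIL import Image

__all__ = [
    "LeafClassSpec",
    "AugmentationConfig",
    "SyntheticDataset",
    "DEFAULT_CLASS_SPECS",
    "CLASS_NAMES",
    "generate_leaf_image",
    "augment_image",
    "split_sizes",
    "make_dataset",
    "mean_color_classifier_accuracy",
]

SPOT_SHAPES = {"round", "snake_eye", "v_shape", "spindle", "strip", "shrink", "none"}


@dataclass(frozen=True)
class LeafClassSpec:
    """Parametric description of one leaf class's lesion appearance."""

    class_name: str
    spot_shape: str
    spot_color: tuple[int, int, int] = (128, 64, 64)
    spot_color_jitter: int = 15
    spot_count_range: tuple[int, int] = (3, 8)
    spot_radius_range: tuple[int, int] = (6, 18)
    background_hue: tuple[float, float] = (0.22, 0.36)  # HSV green band
    ring_color: tuple[int, int, int] | None = None  # snake-eye margin

    def __post_init__(self) -> None:
        if self.spot_shape not in SPOT_SHAPES:
            raise ValueError(f"unknown spot_shape {self.spot_shape!r}")
        if (self.spot_shape == "none") != (self.class_name == "healthy"):
            raise ValueError("spot_shape 'none' is reserved for the healthy class")
        if self.spot_shape != "none" and self.spot_count_range[0] < 1:
            raise ValueError("diseased classes need at least one spot")


DEFAULT_CLASS_SPECS: tuple[LeafClassSpec, ...] = (
    LeafClassSpec("healthy", "none", spot_count_range=(0, 0)),
    LeafClassSpec(
        "powdery_mildew", "round",
        spot_color=(235, 235, 225), spot_count_range=(4, 9),
        spot_radius_range=(6, 14),
    ),
    LeafClassSpec(
        "leaf_spot", "snake_eye",
        spot_color=(150, 150, 150), ring_color=(120, 40, 70),
        spot_count_range=(4, 9), spot_radius_range=(5, 11),
    ),
    LeafClassSpec(
        "botrytis_cinerea", "v_shape",
        spot_color=(150, 110, 45), spot_count_range=(1, 3),
        spot_radius_range=(18, 40),
    ),
    LeafClassSpec(
        "anthracnose", "spindle",
        spot_color=(120, 55, 35), spot_count_range=(3, 7),
        spot_radius_range=(8, 18),
    ),
    LeafClassSpec(
        "verticillium_wilt", "strip",
        spot_color=(170, 140, 60), spot_count_range=(2, 5),
        spot_radius_range=(12, 30),
    ),
    LeafClassSpec(
        "leaf_scorch", "shrink",
        spot_color=(105, 45, 90), spot_count_range=(5, 12),
        spot_radius_range=(4, 10),
    ),
)

CLASS_NAMES: tuple[str, ...] = tuple(s.class_name for s in DEFAULT_CLASS_SPECS)


@dataclass(frozen=True)
class AugmentationConfig:
    """Rotation / flip / random-crop / brightness augmentation parameters."""

    rotation_degrees: tuple[float, float] = (-15.0, 15.0)
    horizontal_flip: float = 0.5
    crop_fraction: float = 0.9
    brightness_factor: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        if not 0.0 < self.crop_fraction <= 1.0:
            raise ValueError("crop_fraction must be in (0, 1]")
        if min(self.brightness_factor) <= 0:
            raise ValueError("brightness factors must be positive")
        if not 0.0 <= self.horizontal_flip <= 1.0:
            raise ValueError("horizontal_flip must be a probability")


@dataclass
class SyntheticDataset:
    """Synthetic image collection with labels and a 3:1:1 split assignment."""

    images: list[np.ndarray]
    labels: np.ndarray
    seed: int
    split_assignment: list[str]
    class_names: tuple[str, ...] = CLASS_NAMES

    def subset(self, split: str) -> tuple[list[np.ndarray], np.ndarray]:
        idx = [i for i, s in enumerate(self.split_assignment) if s == split]
        return [self.images[i] for i in idx], self.labels[idx]


def _rng_for(spec: LeafClassSpec, size: tuple[int, int], seed: int) -> np.random.Generator:
    # Mix the class name into the stream so per-class images with a shared
    # seed are still distinct; crc32 keeps it platform-stable.
    tag = zlib.crc32(spec.class_name.encode())
    return np.random.default_rng([seed & 0x7FFFFFFF, tag, size[0], size[1]])


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - f * s), v * (1 - (1 - f) * s)
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.array(rgb)


def _leaf_background(
    spec: LeafClassSpec, size: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    h, w = size
    hue = rng.uniform(*spec.background_hue)
    base = _hsv_to_rgb(hue, rng.uniform(0.62, 0.72), rng.uniform(0.5, 0.58)) * 255
    img = np.empty((h, w, 3), dtype=np.float64)
    ys, xs = np.mgrid[0:h, 0:w]
    shade = 0.85 + 0.3 * (xs + ys) / (h + w)  # soft diagonal illumination
    img[:] = base[None, None, :] * shade[:, :, None]
    # Vein texture: a midrib plus lateral veins, slightly lighter.
    cx = w / 2
    vein = np.abs(xs - cx) < max(1, w // 96)
    for k in range(1, 5):
        yk = k * h / 5
        slope = (-1) ** k * 0.6
        vein |= np.abs((ys - yk) - slope * (xs - cx)) < 1.2
    img[vein] *= 1.18
    img += rng.normal(0.0, 4.0, size=img.shape)
    return img


def _disk(ys, xs, cy, cx, r) -> np.ndarray:
    return (ys - cy) ** 2 + (xs - cx) ** 2 <= r**2


def _spot_mask(
    shape: str,
    size: tuple[int, int],
    cy: float,
    cx: float,
    r: float,
    angle: float,
    ys: np.ndarray,
    xs: np.ndarray,
) -> np.ndarray:
    if shape in ("round", "shrink"):
        return _disk(ys, xs, cy, cx, r)
    if shape == "snake_eye":
        return _disk(ys, xs, cy, cx, r)
    if shape in ("spindle", "strip"):
        # Rotated ellipse; spindles are 3:1, strips 6:1 elongated.
        ratio = 3.0 if shape == "spindle" else 6.0
        ca, sa = np.cos(angle), np.sin(angle)
        u = (xs - cx) * ca + (ys - cy) * sa
        v = -(xs - cx) * sa + (ys - cy) * ca
        return (u / r) ** 2 + (v / (r / ratio)) ** 2 <= 1.0
    if shape == "v_shape":
        # Wedge opening from the spot center: inside radius and within a
        # ~50-degree angular sector around `angle`.
        dy, dx = ys - cy, xs - cx
        inside = dy**2 + dx**2 <= r**2
        theta = np.arctan2(dy, dx)
        diff = np.angle(np.exp(1j * (theta - angle)))
        return inside & (np.abs(diff) < np.deg2rad(25))
    raise ValueError(f"unknown spot_shape {shape!r}")


def generate_leaf_image(
    spec: LeafClassSpec,
    size: tuple[int, int] = (224, 224),
    seed: int = 0,
    return_mask: bool = False,
):
    """Render one synthetic leaf image (and optionally its lesion mask).

    Byte-identical for identical ``(spec, size, seed)``.
    """
    if size[0] < 32 or size[1] < 32:
        raise ValueError("size must be at least 32x32")
    rng = _rng_for(spec, size, seed)
    h, w = size
    img = _leaf_background(spec, size, rng)
    mask = np.zeros((h, w), dtype=bool)
    ys, xs = np.mgrid[0:h, 0:w]
    if spec.spot_shape != "none":
        n_spots = int(rng.integers(spec.spot_count_range[0], spec.spot_count_range[1] + 1))
        scale = min(h, w) / 224.0
        for _ in range(n_spots):
            cy = rng.uniform(0.1 * h, 0.9 * h)
            cx = rng.uniform(0.1 * w, 0.9 * w)
            r = rng.uniform(*spec.spot_radius_range) * max(scale, 0.45)
            angle = rng.uniform(0, 2 * np.pi)
            m = _spot_mask(spec.spot_shape, size, cy, cx, r, angle, ys, xs)
            color = np.array(spec.spot_color, dtype=np.float64)
            color = color + rng.uniform(-spec.spot_color_jitter, spec.spot_color_jitter, 3)
            img[m] = color[None, :]
            if spec.spot_shape == "snake_eye" and spec.ring_color is not None:
                ring = _disk(ys, xs, cy, cx, r) & ~_disk(ys, xs, cy, cx, 0.6 * r)
                img[ring] = np.asarray(spec.ring_color, dtype=np.float64)[None, :]
            if spec.spot_shape == "shrink":
                # Scorch: darken a halo around the blotch to mimic shrivelling.
                halo = _disk(ys, xs, cy, cx, 1.6 * r) & ~m
                img[halo] *= 0.75
            mask |= m
    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if return_mask:
        return out, mask
    return out


def augment_image(
    img: np.ndarray, config: AugmentationConfig, seed: int = 0
) -> np.ndarray:
    """Rotate / flip / random-crop / brightness-scale, then resize back.

    Output size equals input size (the standard network input); brightness is
    per-pixel multiplication clipped to [0, 255].
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty image")
    h, w = img.shape[:2]
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    angle = rng.uniform(*config.rotation_degrees)
    do_flip = rng.uniform() < config.horizontal_flip
    frac = config.crop_fraction
    ch, cw = max(1, int(round(h * frac))), max(1, int(round(w * frac)))
    if ch < 1 or cw < 1:
        raise ValueError("degenerate crop window")
    y0 = int(rng.integers(0, h - ch + 1))
    x0 = int(rng.integers(0, w - cw + 1))
    factor = rng.uniform(*config.brightness_factor)

    pil = Image.fromarray(img)
    if angle != 0.0:
        pil = pil.rotate(angle, resample=Image.BILINEAR)
    if do_flip:
        pil = pil.transpose(Image.FLIP_LEFT_RIGHT)
    if frac < 1.0:
        pil = pil.crop((x0, y0, x0 + cw, y0 + ch))
    if pil.size != (w, h):
        pil = pil.resize((w, h), resample=Image.BILINEAR)
    out = np.asarray(pil, dtype=np.float64) * factor
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def split_sizes(n_total: int, ratio: tuple[int, int, int] = (3, 1, 1)) -> tuple[int, int, int]:
    """Train/test/validation sizes under a 3:1:1-style ratio.

    The two small partitions are rounded (half-up) to the nearest integer and
    the remainder goes to the training set; components always sum to n_total.
    """
    if any(r <= 0 for r in ratio):
        raise ValueError("ratio components must be positive")
    total_ratio = sum(ratio)
    if n_total < total_ratio:
        raise ValueError(f"n_total={n_total} smaller than ratio sum {total_ratio}")
    n_test = int(np.floor(n_total * ratio[1] / total_ratio + 0.5))
    n_val = int(np.floor(n_total * ratio[2] / total_ratio + 0.5))
    n_train = n_total - n_test - n_val
    if min(n_train, n_test, n_val) < 1:
        raise ValueError("degenerate split")
    return n_train, n_test, n_val


def make_dataset(
    per_class: int = 10,
    size: tuple[int, int] = (224, 224),
    seed: int = 0,
    class_specs: Sequence[LeafClassSpec] = DEFAULT_CLASS_SPECS,
    ratio: tuple[int, int, int] = (3, 1, 1),
) -> SyntheticDataset:
    """Generate a class-balanced synthetic dataset with a stratified split."""
    images: list[np.ndarray] = []
    labels: list[int] = []
    splits: list[str] = []
    n_train, n_test, n_val = split_sizes(per_class, ratio)
    tags = ["train"] * n_train + ["test"] * n_test + ["validation"] * n_val
    for label, spec in enumerate(class_specs):
        for k in range(per_class):
            images.append(generate_leaf_image(spec, size, seed=seed * 100003 + k))
            labels.append(label)
            splits.append(tags[k])
    return SyntheticDataset(
        images=images,
        labels=np.array(labels, dtype=np.int64),
        seed=seed,
        split_assignment=splits,
        class_names=tuple(s.class_name for s in class_specs),
    )


def mean_color_classifier_accuracy(dataset: SyntheticDataset) -> float:
    """Accuracy of a nearest-class-mean-color classifier (train -> test).

    A sanity floor: generated classes must be separable well above chance
    before any network training test is meaningful.
    """
    train_imgs, train_y = dataset.subset("train")
    test_imgs, test_y = dataset.subset("test")
    feats = lambda ims: np.stack([im.reshape(-1, 3).mean(axis=0) for im in ims])
    ftr, fte = feats(train_imgs), feats(test_imgs)
    classes = np.unique(train_y)
    centroids = np.stack([ftr[train_y == c].mean(axis=0) for c in classes])
    d = ((fte[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    pred = classes[d.argmin(axis=1)]
    return float((pred == test_y).mean())
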