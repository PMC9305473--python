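"""Local color correlogram features for the color branch.

A color correlogram is a table indexed by color pairs <i, j> counting how
often color j occurs at a fixed spatial distance d from a pixel of color i.
Restricting to a single fixed distance (d = 1 is the literal 8-neighbourhood)
keeps the table cheap while capturing the local color co-occurrence structure
that distinguishes lesion palettes. Channels are processed independently and
stacked; a merged single-table mode is provided for the variant that keys the
table on value alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = [
    "QuantizedImage",
    "ColorCorrelogram",
    "quantize",
    "compute_correlogram",
    "normalize_correlogram",
    "render_feature_map",
    "color_feature_map",
]

# Chebyshev-distance-d offsets in the 8 compass directions, (dy, dx).
_DIRECTIONS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class QuantizedImage:
    """Integer raster with values in [0, levels)."""

    data: np.ndarray  # H x W x N
    levels: int

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]


@dataclass
class ColorCorrelogram:
    """N stacked Q x Q co-occurrence tables at fixed spatial distance."""

    table: np.ndarray  # N x Q x Q
    distance: int
    levels: int
    normalized: bool = False


def quantize(img: np.ndarray, levels: int = 64) -> QuantizedImage:
    """Uniformly quantize 8-bit values: v -> floor(v * Q / 256).

    ``levels=256`` is the identity. Gray images are treated as one channel.
    """
    if not 2 <= levels <= 256:
        raise ValueError(f"levels must be in [2, 256], got {levels}")
    img = np.asarray(img)
    if img.ndim == 2:
        img = img[:, :, None]
    if img.ndim != 3:
        raise ValueError(f"expected HxW or HxWxN image, got shape {img.shape}")
    data = (img.astype(np.int64) * levels) // 256
    return QuantizedImage(data=data.astype(np.int64), levels=levels)


def compute_correlogram(img: QuantizedImage, distance: int = 1) -> ColorCorrelogram:
    """Count ordered color pairs over the 8 compass neighbours at distance d.

    For every pixel and each of its 8 neighbours at Chebyshev distance d that
    fall inside the image, the cell ``table[t][color_i, color_j]`` is
    incremented; out-of-bounds neighbours are skipped (no padding).
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    data = img.data
    if data.size == 0:
        raise ValueError("empty image")
    h, w, n = data.shape
    q = img.levels
    table = np.zeros((n, q, q), dtype=np.int64)
    for dy, dx in _DIRECTIONS:
        dy, dx = dy * distance, dx * distance
        ys = slice(max(0, -dy), min(h, h - dy))
        xs = slice(max(0, -dx), min(w, w - dx))
        ysn = slice(max(0, dy), min(h, h + dy))
        xsn = slice(max(0, dx), min(w, w + dx))
        ci = data[ys, xs, :]
        cj = data[ysn, xsn, :]
        if ci.size == 0:
            continue
        for t in range(n):
            np.add.at(table[t], (ci[:, :, t].ravel(), cj[:, :, t].ravel()), 1)
    return ColorCorrelogram(table=table, distance=distance, levels=q)


def merge_channels(cgram: ColorCorrelogram) -> ColorCorrelogram:
    """Collapse per-channel tables into one table keyed on value alone."""
    merged = cgram.table.sum(axis=0, keepdims=True)
    return ColorCorrelogram(
        table=merged, distance=cgram.distance, levels=cgram.levels, normalized=False
    )


def normalize_correlogram(cgram: ColorCorrelogram) -> ColorCorrelogram:
    """Divide each channel table by its own total; all-zero tables pass through."""
    table = cgram.table.astype(np.float64)
    totals = table.sum(axis=(1, 2), keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    return ColorCorrelogram(
        table=table / safe,
        distance=cgram.distance,
        levels=cgram.levels,
        normalized=True,
    )


def render_feature_map(
    cgram: ColorCorrelogram, out_size: tuple[int, int] = (224, 224), eps: float = 1e-6
) -> np.ndarray:
    """Render a normalized correlogram as a network-input-sized image.

    Correlogram mass concentrates on the diagonal, so each channel table is
    log-scaled (log(1 + p/eps)), min-max scaled to [0, 255] and resized; three
    channels stack into an RGB raster, one channel is replicated.
    """
    if not cgram.normalized:
        cgram = normalize_correlogram(cgram)
    h, w = out_size
    channels = []
    for t in range(cgram.table.shape[0]):
        mat = np.log1p(cgram.table[t] / eps)
        lo, hi = mat.min(), mat.max()
        scaled = np.zeros_like(mat) if hi <= lo else (mat - lo) / (hi - lo) * 255.0
        img = Image.fromarray(scaled.astype(np.uint8), mode="L")
        img = img.resize((w, h), resample=Image.BILINEAR)
        channels.append(np.asarray(img))
    if len(channels) == 1:
        channels = channels * 3
    return np.stack(channels[:3], axis=2).astype(np.uint8)


def color_feature_map(
    img: np.ndarray,
    levels: int = 64,
    distance: int = 1,
    out_size: tuple[int, int] = (224, 224),
) -> np.ndarray:
    """End-to-end color branch input: quantize -> correlogram -> render."""
    q = quantize(img, levels)
    cg = compute_correlogram(q, distance)
    return render_feature_map(normalize_correlogram(cg), out_size)
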