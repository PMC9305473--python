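"""Area-compensated rotation-invariant local binary patterns (ACRI-LBP).

The texture descriptor driving the texture branch of the network. A circular
LBP code is computed per pixel (P points on a radius-R ring, bilinear
interpolation at fractional coordinates), made rotation invariant by taking
the minimum over the cyclic-rotation orbit of the code, and then brightened
by an additive per-region "area gray compensation" value

    Ac = (Agmin / Agmax) * Ag

where Ag, Agmin, Agmax are the mean, minimum and maximum gray levels of the
pixel's (by default 16x16) region. The compensation counteracts the
systematically dark rendering of minimum-orbit codes without altering their
ordering within a region.

Coordinate convention: x is the column index (increasing right), y the row
index (increasing down); images are indexed ``img[y, x]``. Ring point p sits
at ``(xc + R*cos(2*pi*p/P), yc - R*sin(2*pi*p/P))`` so p advances
counter-clockwise in display orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegionStats",
    "SamplingRing",
    "TextureFeatureMap",
    "rgb_to_gray",
    "region_stats",
    "region_compensation",
    "ring_coordinates",
    "bilinear",
    "lbp_code",
    "rotation_sequence",
    "min_rotation",
    "min_rotation_table",
    "acri_lbp_map",
]


@dataclass(frozen=True)
class RegionStats:
    """Gray-level statistics of one region and its compensation value."""

    mean: float
    max: float
    min: float
    compensation: float


@dataclass(frozen=True)
class SamplingRing:
    """P sampling points on a radius-R circle around (xc, yc)."""

    center: tuple[float, float]
    radius: float
    points: np.ndarray  # (P, 2) array of (x, y) coordinates


@dataclass
class TextureFeatureMap:
    """Rotation-invariant code raster plus its region-compensated rendering.

    ``codes`` holds the per-pixel minimum-orbit LBP values (0 on the border
    frame where the ring does not fit); ``compensated`` is codes + region
    compensation clipped to [0, 255] for 8-bit rendering, and
    ``compensated_raw`` the unclipped float raster fed to the network branch.
    """

    codes: np.ndarray
    compensated: np.ndarray
    compensated_raw: np.ndarray
    radius: float
    n_points: int
    region: int


def rgb_to_gray(img: np.ndarray) -> np.ndarray:
    """Convert an H x W x 3 RGB image to ITU-R BT.601 luma, rounded to uint8."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {img.shape}")
    weights = np.array([0.299, 0.587, 0.114])
    gray = img.astype(np.float64) @ weights
    return np.rint(gray).astype(np.uint8)


def region_stats(region: np.ndarray) -> RegionStats:
    """Mean/max/min gray of a tile and its compensation Ac = (min/max)*mean."""
    region = np.asarray(region, dtype=np.float64)
    if region.size == 0:
        raise ValueError("region tile is empty")
    ag = float(region.mean())
    agmax = float(region.max())
    agmin = float(region.min())
    ac = 0.0 if agmax == 0 else (agmin / agmax) * ag
    return RegionStats(mean=ag, max=agmax, min=agmin, compensation=ac)


def region_compensation(gray: np.ndarray, region: int = 16) -> np.ndarray:
    """Per-pixel compensation raster from non-overlapping ``region`` tiles.

    Tiles at the right/bottom edge may be smaller than ``region``.
    """
    gray = np.asarray(gray, dtype=np.float64)
    h, w = gray.shape
    out = np.empty((h, w), dtype=np.float64)
    for y0 in range(0, h, region):
        for x0 in range(0, w, region):
            tile = gray[y0 : y0 + region, x0 : x0 + region]
            out[y0 : y0 + region, x0 : x0 + region] = region_stats(tile).compensation
    return out


def ring_coordinates(xc: float, yc: float, radius: float, n_points: int) -> SamplingRing:
    """Coordinates of ``n_points`` circle samples around (xc, yc)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_points < 4:
        raise ValueError("need at least 4 sampling points")
    p = np.arange(n_points)
    ang = 2.0 * np.pi * p / n_points
    pts = np.stack([xc + radius * np.cos(ang), yc - radius * np.sin(ang)], axis=1)
    return SamplingRing(center=(xc, yc), radius=radius, points=pts)


def bilinear(img: np.ndarray, x: float, y: float) -> float:
    """Bilinearly interpolated gray value at fractional (x, y).

    Uses the unit-spaced four-neighbour matrix product
    ``[x2-x, x-x1] @ [[f(x1,y1), f(x1,y2)], [f(x2,y1), f(x2,y2)]] @ [y2-y, y-y1]``
    with x1 = floor(x), x2 = x1 + 1 (and likewise for y); exact at integer
    grid points.
    """
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    if not (0.0 <= x <= w - 1 and 0.0 <= y <= h - 1):
        raise ValueError(f"coordinate ({x}, {y}) outside image of shape {img.shape}")
    x1 = int(np.floor(x))
    y1 = int(np.floor(y))
    x2, y2 = x1 + 1, y1 + 1
    # Clip the far corner at the image edge; its weight is exactly zero there.
    xe, ye = min(x2, w - 1), min(y2, h - 1)
    m = np.array(
        [
            [img[y1, x1], img[ye, x1]],
            [img[y1, xe], img[ye, xe]],
        ]
    )
    wx = np.array([x2 - x, x - x1])
    wy = np.array([y2 - y, y - y1])
    return float(wx @ m @ wy)


def lbp_code(center: float, neighbors: np.ndarray) -> int:
    """LBP code: bit p set iff neighbors[p] >= center (ties count as 1)."""
    neighbors = np.asarray(neighbors, dtype=np.float64)
    bits = (neighbors >= center).astype(np.int64)
    return int((bits << np.arange(bits.size)).sum())


def _rotl(code: int, k: int, width: int) -> int:
    mask = (1 << width) - 1
    k %= width
    return ((code << k) | (code >> (width - k))) & mask


def rotation_sequence(code: int, width: int = 8) -> list[int]:
    """The width-1 successive cyclic bit-rotations of ``code`` (identity excluded)."""
    if not 0 <= code < (1 << width):
        raise ValueError(f"code {code} does not fit in {width} bits")
    return [_rotl(code, k, width) for k in range(1, width)]


def min_rotation(code: int, width: int = 8) -> int:
    """Minimum value over the full cyclic-rotation orbit of ``code``."""
    if not 0 <= code < (1 << width):
        raise ValueError(f"code {code} does not fit in {width} bits")
    return min(_rotl(code, k, width) for k in range(width))


def min_rotation_table(width: int = 8) -> np.ndarray:
    """Lookup table mapping every width-bit code to its minimum-orbit value."""
    return np.array([min_rotation(c, width) for c in range(1 << width)], dtype=np.int64)


def _ring_samples(gray: np.ndarray, radius: float, n_points: int) -> np.ndarray:
    """(P, H, W) raster of bilinear ring samples; valid only inside the margin."""
    gray = np.asarray(gray, dtype=np.float64)
    h, w = gray.shape
    ring = ring_coordinates(0.0, 0.0, radius, n_points)
    out = np.empty((n_points, h, w), dtype=np.float64)
    ys, xs = np.mgrid[0:h, 0:w]
    for p, (dx, dy) in enumerate(ring.points):
        # Snap near-integer offsets to kill cos/sin noise at axis angles.
        dx = round(dx, 9)
        dy = round(dy, 9)
        x = xs + dx
        y = ys + dy
        x1 = np.floor(x).astype(np.int64)
        y1 = np.floor(y).astype(np.int64)
        fx = x - x1
        fy = y - y1
        x1c = np.clip(x1, 0, w - 1)
        y1c = np.clip(y1, 0, h - 1)
        x2c = np.clip(x1 + 1, 0, w - 1)
        y2c = np.clip(y1 + 1, 0, h - 1)
        out[p] = (
            gray[y1c, x1c] * (1 - fx) * (1 - fy)
            + gray[y1c, x2c] * fx * (1 - fy)
            + gray[y2c, x1c] * (1 - fx) * fy
            + gray[y2c, x2c] * fx * fy
        )
    return out


# Tie tolerance for the sampled >= comparison: interpolated samples carry
# ~1e-13 floating-point noise (weights summing to 1-eps on constant regions),
# while genuine intensity differences are orders of magnitude larger. A bit is
# set when sample >= center - TIE_TOLERANCE.
TIE_TOLERANCE = 1e-9


def lbp_code_map(gray: np.ndarray, radius: float = 3.0, n_points: int = 8) -> np.ndarray:
    """Raw circular-LBP code raster; border pixels without a full ring get 0."""
    gray = np.asarray(gray, dtype=np.float64)
    h, w = gray.shape
    margin = int(np.ceil(radius))
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError(f"radius {radius} too large for image of shape {gray.shape}")
    samples = _ring_samples(gray, radius, n_points)
    bits = samples >= gray[None, :, :] - TIE_TOLERANCE
    codes = np.zeros((h, w), dtype=np.int64)
    for p in range(n_points):
        codes |= bits[p].astype(np.int64) << p
    valid = np.zeros((h, w), dtype=bool)
    valid[margin : h - margin, margin : w - margin] = True
    codes[~valid] = 0
    return codes


def acri_lbp_map(
    gray: np.ndarray,
    radius: float = 3.0,
    n_points: int = 8,
    region: int = 16,
    compensate: bool = True,
) -> TextureFeatureMap:
    """Full ACRI-LBP texture feature map of a gray image.

    ``compensate=False`` yields plain rotation-invariant LBP (the ablation
    comparator): the compensated rasters then equal the code raster.
    """
    raw = lbp_code_map(gray, radius, n_points)
    lut = min_rotation_table(n_points)
    codes = lut[raw]
    margin = int(np.ceil(radius))
    h, w = codes.shape
    interior = np.zeros((h, w), dtype=bool)
    interior[margin : h - margin, margin : w - margin] = True
    codes = np.where(interior, codes, 0)
    if compensate:
        ac = region_compensation(gray, region)
        raw_out = codes + np.where(interior, ac, 0.0)
    else:
        raw_out = codes.astype(np.float64)
    clipped = np.clip(np.rint(raw_out), 0, 255).astype(np.uint8)
    return TextureFeatureMap(
        codes=codes,
        compensated=clipped,
        compensated_raw=raw_out,
        radius=radius,
        n_points=n_points,
        region=region,
    )
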