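"""Multi-directional attention mechanism (MDAM).

Four directional node features are pooled from the fused feature tensor
(horizontal, vertical, left-diagonal, right-diagonal band means), weighted
against each other with graph-attention coefficients

    e_ij = a(W^T h_i, W^T h_j),   alpha_ij = softmax_j(e_ij),
    C_i  = sum_j alpha_ij h_j,

and extended by two secondary-weight strategies applied elementwise to the
(horizontal, vertical) and (left, right diagonal) pairs:

    multiply:  C * C' - min(C, C')          (penalized product)
    max:       max(C, C') + a * min(C, C')  (max with weighted-min supplement)

The elementwise maximum over the four secondary weights supplements each
primary weight; the eight weight features are concatenated, projected by a
1x1 convolution, squashed to a (0,1) gate and applied as a multiplicative
residual (out = F * gate + F), so reweighting never destroys information.

Functional forms of each step are exposed for direct use and oracle testing;
the trainable block is :class:`MDAM`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor, concat

__all__ = [
    "DirectionalProfiles",
    "AttentionParams",
    "PrimaryWeights",
    "SecondaryWeights",
    "MDAMOutput",
    "directional_profiles",
    "attention_aggregate",
    "multiply_strategy",
    "max_strategy",
    "MDAM",
    "mdam_forward",
]

DIRECTIONS = ("horizontal", "vertical", "left_diagonal", "right_diagonal")


@dataclass
class DirectionalProfiles:
    """Four length-C node vectors, one per direction; shape (4, C)."""

    h: np.ndarray

    def __post_init__(self) -> None:
        if self.h.shape[0] != 4:
            raise ValueError("exactly 4 directional nodes expected")


@dataclass
class AttentionParams:
    """GAT-style scoring parameters: shared map W and scoring vector a."""

    W: np.ndarray  # (C, F')
    a: np.ndarray  # (2 F',)
    leaky_slope: float = 0.2
    alpha: float = 0.3  # max-strategy mixing scalar
    e: np.ndarray | None = None  # explicit raw coefficients override (N x N)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.a.shape[0] != 2 * self.W.shape[1]:
            raise ValueError("scoring vector must have length 2*F'")

    @staticmethod
    def init(channels: int, proj: int | None = None, alpha: float = 0.3, seed: int = 0) -> "AttentionParams":
        proj = proj or channels
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(channels)
        return AttentionParams(
            W=rng.uniform(-scale, scale, size=(channels, proj)),
            a=rng.uniform(-scale, scale, size=2 * proj),
            alpha=alpha,
        )


@dataclass
class PrimaryWeights:
    """Aggregated direction features C_i (4, C) and softmax coefficients (4, 4)."""

    C: np.ndarray
    coefficients: np.ndarray


@dataclass
class SecondaryWeights:
    C21: np.ndarray
    C22: np.ndarray
    C23: np.ndarray
    C24: np.ndarray


@dataclass
class MDAMOutput:
    """Eight-slab concatenation, the (0,1) gate and the reweighted tensor."""

    concat: np.ndarray  # (8, C, H, W) weight slabs
    gate: np.ndarray  # (H, W) or (N, 1, H, W)
    reweighted: np.ndarray


def direction_weights(h: int, w: int) -> dict[str, np.ndarray]:
    """Per-direction spatial pooling weights (each an HxW array summing to 1).

    Bands (rows, columns, diagonals, anti-diagonals) are weighted equally
    regardless of how many pixels they contain, then pixels share their
    band's weight uniformly.
    """
    ys, xs = np.mgrid[0:h, 0:w]
    out: dict[str, np.ndarray] = {}
    for name, band_id in (
        ("horizontal", ys),
        ("vertical", xs),
        ("left_diagonal", xs - ys),
        ("right_diagonal", xs + ys),
    ):
        ids, counts = np.unique(band_id, return_counts=True)
        n_bands = len(ids)
        weight = np.zeros((h, w))
        for band, count in zip(ids, counts):
            weight[band_id == band] = 1.0 / (n_bands * count)
        out[name] = weight
    return out


def directional_profiles(F: np.ndarray) -> DirectionalProfiles:
    """Pool a C x H x W tensor into four length-C direction node vectors."""
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 3:
        raise ValueError("expected a CxHxW feature tensor")
    c, h, w = F.shape
    if h < 2 or w < 2:
        raise ValueError("spatial extent must be at least 2x2")
    weights = direction_weights(h, w)
    flat = F.reshape(c, h * w)
    hs = [flat @ weights[d].ravel() for d in DIRECTIONS]
    return DirectionalProfiles(h=np.stack(hs))


def attention_aggregate(profiles: DirectionalProfiles, params: AttentionParams) -> PrimaryWeights:
    """Graph-attention aggregation of the four direction nodes."""
    h = profiles.h  # (4, C)
    if params.e is not None:
        e = np.asarray(params.e, dtype=np.float64)
    else:
        wh = h @ params.W  # (4, F')
        fp = params.W.shape[1]
        a1, a2 = params.a[:fp], params.a[fp:]
        s1 = wh @ a1  # (4,)
        s2 = wh @ a2
        e = s1[:, None] + s2[None, :]
        e = np.where(e > 0, e, params.leaky_slope * e)
    if not np.all(np.isfinite(e)):
        raise FloatingPointError("non-finite attention coefficients")
    e = e - e.max(axis=1, keepdims=True)
    exp = np.exp(e)
    coeff = exp / exp.sum(axis=1, keepdims=True)
    return PrimaryWeights(C=coeff @ h, coefficients=coeff)


def multiply_strategy(ca: np.ndarray, cb: np.ndarray) -> np.ndarray:
    """Penalized product: Ca * Cb - min(Ca, Cb), elementwise."""
    ca, cb = np.asarray(ca, dtype=np.float64), np.asarray(cb, dtype=np.float64)
    if ca.shape != cb.shape:
        raise ValueError("shape mismatch")
    return ca * cb - np.minimum(ca, cb)


def max_strategy(ca: np.ndarray, cb: np.ndarray, alpha: float = 0.3) -> np.ndarray:
    """Max matching: max(Ca, Cb) + alpha * min(Ca, Cb), elementwise."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    ca, cb = np.asarray(ca, dtype=np.float64), np.asarray(cb, dtype=np.float64)
    if ca.shape != cb.shape:
        raise ValueError("shape mismatch")
    return np.maximum(ca, cb) + alpha * np.minimum(ca, cb)


def secondary_weights(primary: PrimaryWeights, alpha: float = 0.3) -> SecondaryWeights:
    ch, cv, cld, crd = primary.C
    return SecondaryWeights(
        C21=multiply_strategy(ch, cv),
        C22=max_strategy(ch, cv, alpha),
        C23=multiply_strategy(cld, crd),
        C24=max_strategy(cld, crd, alpha),
    )


class MDAM(nn.Module):
    """Trainable multi-directional attention block.

    Two 3x3 convolutions perform shallow mining before the directional
    pooling; the attention parameters (W, a) and the 1x1 gate projection are
    learned jointly with the rest of the network.
    """

    def __init__(
        self,
        channels: int,
        alpha: float = 0.3,
        seed: int = 0,
        activation: str = "elu",
        leaky_slope: float = 0.2,
    ):
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        rng = np.random.default_rng(seed)
        self.alpha = alpha
        self.leaky_slope = leaky_slope
        self.mine = nn.Sequential(
            nn.Conv2d(channels, channels, 3, padding=1, rng=rng),
            nn.Activation(activation),
            nn.Conv2d(channels, channels, 3, padding=1, rng=rng),
            nn.Activation(activation),
        )
        scale = 1.0 / np.sqrt(channels)
        self.att_W = Tensor(rng.uniform(-scale, scale, size=(channels, channels)), requires_grad=True)
        self.att_a1 = Tensor(rng.uniform(-scale, scale, size=(channels, 1)), requires_grad=True)
        self.att_a2 = Tensor(rng.uniform(-scale, scale, size=(channels, 1)), requires_grad=True)
        self.project = nn.Conv2d(8 * channels, 1, 1, rng=rng)

    def forward(self, x: Tensor, return_parts: bool = False):
        n, c, h, w = x.shape
        mined = self.mine(x)
        weights = direction_weights(h, w)
        flat = mined.reshape(n, c, h * w)
        hs = [flat @ Tensor(weights[d].ravel()[:, None]) for d in DIRECTIONS]  # (n, c, 1)
        hstack = concat([t.transpose((0, 2, 1)) for t in hs], axis=1)  # (n, 4, c)
        wh = hstack @ self.att_W  # (n, 4, c)
        s1 = wh @ self.att_a1  # (n, 4, 1)
        s2 = wh @ self.att_a2
        e = (s1 + s2.transpose((0, 2, 1))).leaky_relu(self.leaky_slope)  # (n, 4, 4)
        exp = e.exp()
        coeff = exp / exp.sum(axis=2, keepdims=True)
        primary = coeff @ hstack  # (n, 4, c)
        ch_, cv_, cld_, crd_ = (primary[:, i, :] for i in range(4))
        c21 = ch_ * cv_ - ch_.minimum(cv_)
        c22 = ch_.maximum(cv_) + self.alpha * ch_.minimum(cv_)
        c23 = cld_ * crd_ - cld_.minimum(crd_)
        c24 = cld_.maximum(crd_) + self.alpha * cld_.minimum(crd_)
        supplement = c21.maximum(c22).maximum(c23.maximum(c24))
        slab_vecs = [ch_ + supplement, cv_ + supplement, cld_ + supplement, crd_ + supplement,
                     c21, c22, c23, c24]
        ones = Tensor(np.ones((1, 1, h, w)))
        slabs = [(v.reshape(n, c, 1, 1)) * ones for v in slab_vecs]  # (n, c, h, w) each
        stacked = concat(slabs, axis=1)  # (n, 8c, h, w)
        gate = self.project(stacked).sigmoid()  # (n, 1, h, w)
        out = x * gate + x
        if return_parts:
            return out, stacked, gate
        return out


def mdam_forward(F: np.ndarray, block: MDAM | None = None, seed: int = 0, alpha: float = 0.3) -> MDAMOutput:
    """Run MDAM on a single C x H x W tensor, returning all intermediates."""
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 3:
        raise ValueError("expected a CxHxW feature tensor")
    c, h, w = F.shape
    if block is None:
        block = MDAM(c, alpha=alpha, seed=seed)
    out, stacked, gate = block(Tensor(F[None]), return_parts=True)
    return MDAMOutput(
        concat=stacked.data[0].reshape(8, c, h, w),
        gate=gate.data[0, 0],
        reweighted=out.data[0],
    )
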