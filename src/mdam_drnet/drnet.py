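"""MDAM-DRNet: dual-channel residual network assembly and training.

Two front-end branches compute network-input-sized feature images from the
raw leaf photo — a color-correlogram rendering and an ACRI-LBP texture map —
and feed independent copies of ResNeXt stages 1-2. The branch outputs are
channel-concatenated, reweighted by the multi-directional attention block,
and passed through shared stages 3-4, global average pooling and a softmax
head. ELU replaces ReLU throughout; the network uses no batch normalization
(ELU keeps deep stacks trainable without it).

The default layout is ResNeXt-50 (32x4d): stage block counts (3, 4, 6, 3),
cardinality 32, stage output widths (256, 512, 1024, 2048). ``width_mult``
scales every channel count for desk-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image

from . import nn
from .autograd import Tensor, concat, softmax, softmax_cross_entropy
from .color_path import color_feature_map
from .mdam import MDAM
from .texture_path import acri_lbp_map, rgb_to_gray

__all__ = ["NetworkConfig", "elu", "build_network", "MDAMDRNet", "forward", "train_network"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and training-relevant hyperparameters."""

    input_size: int = 224
    num_classes: int = 7
    cardinality: int = 32
    stage_blocks: tuple[int, int, int, int] = (3, 4, 6, 3)
    width_mult: float = 1.0
    elu_alpha: float = 1.0
    mdam_alpha: float = 0.3
    activation: str = "elu"
    use_color_branch: bool = True
    use_texture_branch: bool = True
    use_mdam: bool = True
    quant_levels: int = 64
    correlogram_distance: int = 1
    lbp_radius: float = 3.0
    lbp_points: int = 8
    lbp_region: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValueError("need at least two classes")
        if self.elu_alpha <= 0:
            raise ValueError("elu_alpha must be positive")
        if not self.use_color_branch and not self.use_texture_branch:
            # backbone-only variant: single branch on the raw image
            pass


def elu(x: float, alpha: float = 1.0) -> float:
    """Exponential linear unit: x for x > 0, alpha*(e^x - 1) otherwise."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return float(x) if x > 0 else float(alpha * (np.exp(x) - 1.0))


# Stage output widths and grouped-bottleneck widths of ResNeXt-50 (32x4d).
_STAGE_OUT = (256, 512, 1024, 2048)
_STAGE_MID = (128, 256, 512, 1024)


def _scaled(width: float, mult: float, cardinality: int) -> int:
    """Scale a channel count, keeping it a positive multiple of cardinality."""
    w = max(cardinality, int(round(width * mult / cardinality)) * cardinality)
    return w


class _Bottleneck(nn.Module):
    """ResNeXt bottleneck: 1x1 -> grouped 3x3 -> 1x1 with residual shortcut.

    A projection shortcut (the "convolution block") is used whenever the
    input width or stride changes; otherwise it is an identity block.
    """

    def __init__(self, cin, cout, cmid, cardinality, stride, act, rng):
        self.conv1 = nn.Conv2d(cin, cmid, 1, rng=rng)
        self.conv2 = nn.Conv2d(cmid, cmid, 3, stride=stride, padding=1, groups=cardinality, rng=rng)
        self.conv3 = nn.Conv2d(cmid, cout, 1, rng=rng)
        self.act = act
        if cin != cout or stride != 1:
            self.shortcut = nn.Conv2d(cin, cout, 1, stride=stride, rng=rng)
        else:
            self.shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.act(self.conv1(x))
        y = self.act(self.conv2(y))
        y = self.conv3(y)
        s = x if self.shortcut is None else self.shortcut(x)
        return self.act(y + s)


def _make_stage(cin, cout, cmid, blocks, cardinality, stride, act, rng) -> nn.Sequential:
    layers = [_Bottleneck(cin, cout, cmid, cardinality, stride, act, rng)]
    for _ in range(blocks - 1):
        layers.append(_Bottleneck(cout, cout, cmid, cardinality, 1, act, rng))
    return nn.Sequential(*layers)


class _Branch(nn.Module):
    """Stem + stages 1-2 of ResNeXt with independent parameters."""

    def __init__(self, in_channels, cfg: NetworkConfig, act, rng):
        card = cfg.cardinality
        stem_out = _scaled(64, cfg.width_mult, 1)
        out1 = _scaled(_STAGE_OUT[0], cfg.width_mult, card)
        out2 = _scaled(_STAGE_OUT[1], cfg.width_mult, card)
        mid1 = _scaled(_STAGE_MID[0], cfg.width_mult, card)
        mid2 = _scaled(_STAGE_MID[1], cfg.width_mult, card)
        self.stem = nn.Sequential(
            nn.Conv2d(in_channels, stem_out, 7, stride=2, padding=3, rng=rng),
            nn.Activation(cfg.activation, cfg.elu_alpha),
            nn.MaxPool2d(2),
        )
        self.stage1 = _make_stage(stem_out, out1, mid1, cfg.stage_blocks[0], card, 1, act, rng)
        self.stage2 = _make_stage(out1, out2, mid2, cfg.stage_blocks[1], card, 2, act, rng)
        self.out_channels = out2

    def forward(self, x: Tensor) -> Tensor:
        return self.stage2(self.stage1(self.stem(x)))


class MDAMDRNet(nn.Module):
    """The assembled dual-channel network."""

    def __init__(self, config: NetworkConfig):
        cfg = config
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        act_mod = nn.Activation(cfg.activation, cfg.elu_alpha)
        act = act_mod
        card = cfg.cardinality

        self.branches: list[_Branch] = []
        self.branch_inputs: list[str] = []
        if cfg.use_color_branch:
            self.branches.append(_Branch(3, cfg, act, rng))
            self.branch_inputs.append("color")
        if cfg.use_texture_branch:
            self.branches.append(_Branch(1, cfg, act, rng))
            self.branch_inputs.append("texture")
        if not self.branches:
            self.branches.append(_Branch(3, cfg, act, rng))
            self.branch_inputs.append("raw")

        fused = sum(b.out_channels for b in self.branches)
        self.mdam = MDAM(fused, alpha=cfg.mdam_alpha, seed=cfg.seed + 1,
                         activation=cfg.activation) if cfg.use_mdam else None

        out3 = _scaled(_STAGE_OUT[2], cfg.width_mult, card)
        out4 = _scaled(_STAGE_OUT[3], cfg.width_mult, card)
        mid3 = _scaled(_STAGE_MID[2], cfg.width_mult, card)
        mid4 = _scaled(_STAGE_MID[3], cfg.width_mult, card)
        self.stage3 = _make_stage(fused, out3, mid3, cfg.stage_blocks[2], card, 2, act, rng)
        self.stage4 = _make_stage(out3, out4, mid4, cfg.stage_blocks[3], card, 2, act, rng)
        self.head = nn.Linear(out4, cfg.num_classes, rng=rng)
        self._feature_cache: dict[bytes, list[np.ndarray]] = {}

    # -- front-end feature images -------------------------------------------
    def _branch_inputs_for(self, img: np.ndarray) -> list[np.ndarray]:
        """Per-branch network inputs (CHW floats in [0, 1]) for one image."""
        img = np.asarray(img)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"expected an HxWx3 RGB image, got shape {img.shape}")
        key = img.tobytes()
        cached = self._feature_cache.get(key)
        if cached is not None:
            return cached
        cfg = self.config
        size = (cfg.input_size, cfg.input_size)
        out: list[np.ndarray] = []
        for kind in self.branch_inputs:
            if kind == "color":
                fmap = color_feature_map(
                    img, cfg.quant_levels, cfg.correlogram_distance, size
                )
                out.append(fmap.transpose(2, 0, 1).astype(np.float64) / 255.0)
            elif kind == "texture":
                tex = acri_lbp_map(
                    rgb_to_gray(img), cfg.lbp_radius, cfg.lbp_points, cfg.lbp_region
                ).compensated_raw
                pil = Image.fromarray(np.clip(tex, 0, 255).astype(np.uint8), mode="L")
                pil = pil.resize(size[::-1], resample=Image.BILINEAR)
                out.append(np.asarray(pil, dtype=np.float64)[None, :, :] / 255.0)
            else:  # raw
                pil = Image.fromarray(img.astype(np.uint8))
                if pil.size != size[::-1]:
                    pil = pil.resize(size[::-1], resample=Image.BILINEAR)
                out.append(np.asarray(pil, dtype=np.float64).transpose(2, 0, 1) / 255.0)
        if len(self._feature_cache) < 4096:
            self._feature_cache[key] = out
        return out

    def prepare_batch(self, images: list[np.ndarray]) -> list[Tensor]:
        """Stack per-branch inputs for a batch of raw images."""
        per_branch = [[] for _ in self.branches]
        for img in images:
            for slot, arr in zip(per_branch, self._branch_inputs_for(img)):
                slot.append(arr)
        return [Tensor(np.stack(slot)) for slot in per_branch]

    # -- forward -------------------------------------------------------------
    def forward_features(self, branch_tensors: list[Tensor]) -> Tensor:
        feats = [branch(t) for branch, t in zip(self.branches, branch_tensors)]
        fused = feats[0] if len(feats) == 1 else concat(feats, axis=1)
        if self.mdam is not None:
            fused = self.mdam(fused)
        y = self.stage4(self.stage3(fused))
        pooled = y.mean(axis=(2, 3))
        return self.head(pooled)

    def logits(self, images: list[np.ndarray]) -> Tensor:
        return self.forward_features(self.prepare_batch(images))

    def predict_proba(self, images: list[np.ndarray]) -> np.ndarray:
        return softmax(self.logits(images).data, axis=1)

    def predict(self, images: list[np.ndarray]) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)


def build_network(config: NetworkConfig) -> MDAMDRNet:
    """Construct the network described by ``config``."""
    return MDAMDRNet(config)


def forward(network: MDAMDRNet, img: np.ndarray) -> np.ndarray:
    """Class posterior for one raw RGB image (deterministic in eval mode)."""
    probs = network.predict_proba([img])[0]
    return probs


@dataclass
class TrainResult:
    losses: list[float]
    network: MDAMDRNet


def _lr_at(base_lr: float, epoch: int) -> float:
    """Step decay: /10 after epoch 60 and again after epoch 140."""
    lr = base_lr
    if epoch >= 60:
        lr /= 10.0
    if epoch >= 140:
        lr /= 10.0
    return lr


def train_network(
    network: MDAMDRNet,
    images: list[np.ndarray],
    labels: np.ndarray,
    epochs: int = 10,
    batch_size: int = 24,
    lr: float = 1e-4,
    weight_decay: float = 5e-4,
    optimizer: str = "adam",
    seed: int = 0,
) -> TrainResult:
    """Mini-batch training with cross-entropy; returns per-epoch mean losses."""
    params = network.parameters()
    if optimizer == "adam":
        opt = nn.Adam(params, lr=lr, weight_decay=weight_decay)
    elif optimizer == "sgd":
        opt = nn.SGD(params, lr=lr, momentum=0.9, weight_decay=weight_decay)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")
    rng = np.random.default_rng(seed)
    n = len(images)
    labels = np.asarray(labels)
    losses: list[float] = []
    for epoch in range(epochs):
        opt.lr = _lr_at(lr, epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            batch = [images[i] for i in idx]
            logits = network.logits(batch)
            loss = softmax_cross_entropy(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
    return TrainResult(losses=losses, network=network)
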