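"""The residual U-Net for 3-class cross-section segmentation.

Architecture: an encoder of ``depth`` residual blocks (two 3x3 convolutions
with batch normalization and ReLU, plus a 1x1 strided convolution on the
residual branch).  All but the deepest block halve the spatial size with
stride-2 convolutions, so a 128 px patch reaches a 4 px deepest feature map
at depth 6; channel width doubles per level starting from ``base_filters``.
The decoder mirrors the encoder with stride-2 transposed convolutions,
concatenating the matching encoder skip at each resolution, and a final 1x1
convolution maps to the 3 output channels (background / wall / lumen).

Training recipe: Adam (initial learning rate 0.001),
channel-wise sigmoid + binary cross-entropy against one-hot targets, 200
epochs, and augmentation with rotations in [0, 180] deg, up to 5 px
translation per axis and scaling in [0.9, 1.1].  Inference takes the argmax
over the three channel probabilities with dropout off and batch norm in
inference mode, so predictions are deterministic.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import nnet
from .annotation import LabelMask
from .geometry import CrossSection
from .nnet import Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Dropout, Layer, ReLU

logger = logging.getLogger(__name__)

N_CLASSES = 3


@dataclass
class NetConfig:
    """Residual U-Net hyperparameters (defaults = the selected model)."""

    depth: int = 6
    base_filters: int = 16
    dropout: float = 0.1
    in_channels: int = 1
    out_channels: int = N_CLASSES
    n_px: int = 128
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_px % 2 ** (self.depth - 1) != 0:
            raise ValueError(
                f"n_px={self.n_px} must be divisible by 2^(depth-1)={2 ** (self.depth - 1)}"
            )


@dataclass
class AugmentConfig:
    """Random rigid-plus-scale augmentation ranges."""

    rot_deg: tuple[float, float] = (0.0, 180.0)
    trans_px: int = 5
    scale: tuple[float, float] = (0.9, 1.1)
    enabled: bool = True


@dataclass
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 200
    batch_size: int = 16
    seed: int = 0
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    loss: str = "bce"
    prior_bias_init: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.lr <= 0:
            raise ValueError("epochs >= 1 and lr > 0 required")
        if self.loss not in nnet.LOSSES:
            raise ValueError(f"unknown loss {self.loss!r}")


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------


class ResBlock(Layer):
    """conv3x3(stride) -> BN -> ReLU -> conv3x3 -> BN, plus a 1x1 strided
    convolution on the residual branch; ReLU and dropout after the sum."""

    def __init__(self, in_ch, out_ch, stride, dropout, rng, dtype):
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride, rng, dtype)
        self.bn1 = BatchNorm2d(out_ch, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, 1, rng, dtype)
        self.bn2 = BatchNorm2d(out_ch, dtype=dtype)
        # zero-init the last normalization gain so each block starts as its
        # shortcut alone; standard residual-network practice that speeds up
        # early optimization
        self.bn2.gamma.value[...] = 0.0
        self.shortcut = Conv2d(in_ch, out_ch, 1, stride, rng, dtype)
        self.relu_out = ReLU()
        self.drop = Dropout(dropout, rng)

    def params(self):
        out = []
        for layer in (self.conv1, self.bn1, self.conv2, self.bn2, self.shortcut):
            out.extend(layer.params())
        return out

    def forward(self, x, train=True):
        main = self.conv1.forward(x, train)
        main = self.bn1.forward(main, train)
        main = self.relu1.forward(main, train)
        main = self.conv2.forward(main, train)
        main = self.bn2.forward(main, train)
        short = self.shortcut.forward(x, train)
        out = self.relu_out.forward(main + short, train)
        return self.drop.forward(out, train)

    def backward(self, grad):
        grad = self.drop.backward(grad)
        grad = self.relu_out.backward(grad)
        d_main = self.bn2.backward(grad)
        d_main = self.conv2.backward(d_main)
        d_main = self.relu1.backward(d_main)
        d_main = self.bn1.backward(d_main)
        d_main = self.conv1.backward(d_main)
        d_short = self.shortcut.backward(grad)
        return d_main + d_short


class UpBlock(Layer):
    """Stride-2 transposed convolution, skip concatenation, residual block."""

    def __init__(self, in_ch, skip_ch, out_ch, dropout, rng, dtype):
        self.skip_ch = skip_ch
        self.up = ConvTranspose2d(in_ch, max(skip_ch, out_ch), rng, dtype)
        self.block = ResBlock(max(skip_ch, out_ch) + skip_ch, out_ch, 1, dropout, rng, dtype)

    def params(self):
        return self.up.params() + self.block.params()

    def forward(self, x, skip, train=True):
        x = self.up.forward(x, train)
        if skip is not None:
            x = np.concatenate([x, skip], axis=1)
        return self.block.forward(x, train)

    def backward(self, grad):
        grad = self.block.backward(grad)
        if self.skip_ch:
            d_skip = grad[:, -self.skip_ch :]
            grad = grad[:, : -self.skip_ch]
        else:
            d_skip = None
        return self.up.backward(grad), d_skip


class ResUNet:
    """The full residual U-Net (see module docstring for the topology)."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(seed)
        ch = [cfg.base_filters * 2**i for i in range(cfg.depth)]
        self.encoder: list[ResBlock] = []
        for i in range(cfg.depth):
            in_ch = cfg.in_channels if i == 0 else ch[i - 1]
            stride = 2 if i < cfg.depth - 1 else 1  # deepest block keeps size
            self.encoder.append(ResBlock(in_ch, ch[i], stride, cfg.dropout, rng, dtype))
        self.decoder: list[UpBlock] = []
        cur = ch[-1]
        for j in range(cfg.depth - 1):
            skip_idx = cfg.depth - 3 - j
            # the last decoder level has no encoder counterpart (the first
            # encoder block already downsamples); it concatenates the network
            # input instead -- the only full-resolution signal available
            skip_ch = ch[skip_idx] if skip_idx >= 0 else cfg.in_channels
            out_ch = ch[skip_idx] if skip_idx >= 0 else cfg.base_filters
            self.decoder.append(UpBlock(cur, skip_ch, out_ch, cfg.dropout, rng, dtype))
            cur = out_ch
        self.head = Conv2d(cur, cfg.out_channels, 1, 1, rng, dtype)
        # small head init: start near uniform class probabilities instead of
        # saturated logits, which speeds up early optimization considerably
        self.head.W.value *= 0.01

    def params(self) -> list[nnet.Param]:
        out = []
        for b in self.encoder:
            out.extend(b.params())
        for b in self.decoder:
            out.extend(b.params())
        out.extend(self.head.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[-1] != self.cfg.n_px or x.shape[-2] != self.cfg.n_px:
            raise ValueError(f"input must be {self.cfg.n_px} px square, got {x.shape[-2:]}")
        net_input = x
        feats = []
        for block in self.encoder:
            x = block.forward(x, train)
            feats.append(x)
        for j, up in enumerate(self.decoder):
            skip_idx = self.cfg.depth - 3 - j
            skip = feats[skip_idx] if skip_idx >= 0 else net_input
            x = up.forward(x, skip, train)
        return self.head.forward(x, train)

    def backward(self, grad: np.ndarray) -> None:
        grad = self.head.backward(grad)
        skip_grads: dict[int, np.ndarray] = {}
        for j in reversed(range(len(self.decoder))):
            grad, d_skip = self.decoder[j].backward(grad)
            skip_idx = self.cfg.depth - 3 - j
            if d_skip is not None:
                skip_grads[skip_idx] = d_skip
        for i in reversed(range(self.cfg.depth)):
            if i in skip_grads:
                grad = grad + skip_grads[i]
            grad = self.encoder[i].backward(grad)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path, metadata: dict | None = None) -> None:
        """Save weights (.npz) with a JSON sidecar holding the config.

        ``metadata`` (e.g. the training configuration and a digest of the
        training data) is stored alongside the network config.
        """
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        bn_state = {}
        idx = 0
        for block in self._all_bn():
            bn_state[f"bn{idx}_mean"] = block.running_mean
            bn_state[f"bn{idx}_var"] = block.running_var
            idx += 1
        np.savez(path.with_suffix(".npz"), **arrays, **bn_state)
        sidecar = {"net": asdict(self.cfg)}
        if metadata:
            sidecar.update(metadata)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))

    def _all_bn(self) -> list[BatchNorm2d]:
        bns = []
        for b in self.encoder:
            bns.extend([b.bn1, b.bn2])
        for u in self.decoder:
            bns.extend([u.block.bn1, u.block.bn2])
        return bns

    @classmethod
    def load(cls, path: str | Path) -> "ResUNet":
        path = Path(path)
        cfg = NetConfig(**json.loads(path.with_suffix(".json").read_text())["net"])
        net = cls(cfg)
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(net.params()):
            p.value[...] = data[f"p{i}"]
        for idx, bn in enumerate(net._all_bn()):
            bn.running_mean = data[f"bn{idx}_mean"]
            bn.running_var = data[f"bn{idx}_var"]
        return net


def build_unet(cfg: NetConfig, seed: int = 0) -> ResUNet:
    """Construct the residual U-Net; layer graph depends only on ``cfg``."""
    return ResUNet(cfg, seed)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One random rotation / translation / scaling of an image-mask pair.

    Rotation is uniform on ``rot_deg``, translation uniform on integer
    pixels in ``[-trans_px, trans_px]`` per axis, scale uniform on ``scale``.
    The image is interpolated bilinearly, the mask with nearest neighbour
    (labels stay integral); out-of-grid pixels are filled with 0/background.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask must share a grid")
    if not cfg.enabled:
        return image, mask
    theta = np.deg2rad(rng.uniform(*cfg.rot_deg))
    t = rng.integers(-cfg.trans_px, cfg.trans_px + 1, size=2)
    f = rng.uniform(*cfg.scale)
    c, s = np.cos(theta), np.sin(theta)
    # output -> input mapping: rotate by -theta and unscale around the center
    m = np.array([[c, -s], [s, c]]) / f
    center = (np.array(image.shape) - 1) / 2.0
    offset = center - m @ (center + t)
    img_out = ndimage.affine_transform(
        image.astype(float), m, offset=offset, order=1, mode="constant", cval=0.0
    )
    mask_out = ndimage.affine_transform(
        mask, m, offset=offset, order=0, mode="constant", cval=0, output=mask.dtype
    )
    return img_out, mask_out


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------


def one_hot(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """(N, H, W) integer labels -> (N, C, H, W) one-hot float array."""
    return np.moveaxis(np.eye(n_classes, dtype=np.float32)[labels], -1, 1)


def train(
    model: ResUNet,
    dataset: Sequence[tuple[CrossSection, LabelMask]],
    cfg: TrainConfig,
) -> list[float]:
    """Train in place; returns the per-epoch mean training loss history.

    The dataset is a sequence of (normalized cross-section, label mask)
    pairs.  Augmentation is applied on the fly per sample and epoch.  A
    fixed seed gives a reproducible run on one device.  NaN loss aborts.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    images = np.stack([cs.image for cs, _ in dataset]).astype(np.float32)
    masks = np.stack([m.labels for _, m in dataset])
    mean_abs = np.abs(images.mean(axis=(1, 2)))
    stds = images.std(axis=(1, 2))
    if np.any(mean_abs > 0.1) or np.any(np.abs(stds - 1) > 0.2):
        warnings.warn("training patches do not look normalized (mean 0 / std 1)", stacklevel=2)

    rng = np.random.default_rng(cfg.seed)
    loss_fn = nnet.LOSSES[cfg.loss]
    if cfg.prior_bias_init and not np.any(model.head.b.value):
        # start the output layer at the logits of the dataset's class
        # frequencies so the first epochs are not spent re-deriving the
        # background/foreground imbalance (prior-initialized output bias)
        freq = one_hot(masks).mean(axis=(0, 2, 3))
        freq = np.clip(freq, 1e-4, 1 - 1e-4)
        model.head.b.value[...] = np.log(freq / (1 - freq)).astype(model.head.b.value.dtype)
    opt = Adam(model.params(), lr=cfg.lr)
    history: list[float] = []
    n = len(dataset)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch_img = np.empty((len(idx), 1, *images.shape[1:]), dtype=np.float32)
            batch_lab = np.empty((len(idx), *masks.shape[1:]), dtype=masks.dtype)
            for j, i in enumerate(idx):
                img, lab = augment(images[i], masks[i], cfg.augmentation, rng)
                batch_img[j, 0] = img
                batch_lab[j] = lab
            logits = model.forward(batch_img, train=True)
            loss, grad = loss_fn(logits, one_hot(batch_lab))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {start // cfg.batch_size}; "
                    f"|logits| max = {np.abs(logits).max():.3g}"
                )
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_losses.append(loss)
        history.append(float(np.mean(epoch_losses)))
        if epoch == 0 or (epoch + 1) % 10 == 0:
            logger.info("epoch %d/%d: loss %.5f", epoch + 1, cfg.epochs, history[-1])
    return history


def predict(model: ResUNet, cs: CrossSection) -> LabelMask:
    """Segment one cross-section: per-pixel argmax over channel probabilities.

    Deterministic: dropout is off and batch norm uses running statistics.
    """
    if cs.image.shape != (model.cfg.n_px, model.cfg.n_px):
        raise ValueError(
            f"cross-section is {cs.image.shape}, model expects {model.cfg.n_px} px"
        )
    if not cs.normalized:
        warnings.warn("predicting on a non-normalized cross-section", stacklevel=2)
    x = cs.image.astype(np.float32)[None, None]
    logits = model.forward(x, train=False)
    labels = np.argmax(logits[0], axis=0).astype(np.uint8)
    return LabelMask(labels, cs.plane.pixel_mm)


def predict_batch(model: ResUNet, sections: Sequence[CrossSection]) -> list[LabelMask]:
    """Vectorized inference over many cross-sections."""
    if not sections:
        return []
    x = np.stack([cs.image for cs in sections]).astype(np.float32)[:, None]
    logits = model.forward(x, train=False)
    labels = np.argmax(logits, axis=1).astype(np.uint8)
    return [LabelMask(lab, cs.plane.pixel_mm) for lab, cs in zip(labels, sections)]
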