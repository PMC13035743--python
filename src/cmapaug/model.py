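"""The 2D U-Net segmentation model, dice loss and volume prediction.

Encoder-decoder with skip connections: each stage applies two 3x3
zero-padded convolutions, each followed by batch normalization and ReLU;
2x2 max pooling halves the resolution between encoder stages and a 2x2
stride-2 transposed convolution (or nearest-upsample + convolution) doubles
it on the way up, with the symmetric encoder feature map concatenated before
each decoder stage.  Zero padding keeps the output spatial size equal to the
input.  A 1x1 convolution produces a single foreground logit per pixel; the
soft dice loss on the sigmoid probabilities drives Adam optimization.

Feature widths double per stage from ``base_width`` (64 at clinical scale,
configurable down to 8 or less for desk-scale runs).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .nn import (Adam, BatchNorm2d, Conv1x1, Conv2d, ConvTranspose2d, Layer,
                 MaxPool2d, ReLU, Sequential, sigmoid)
from .preprocessing import GrayVolume, MaskVolume

__all__ = [
    "SegModelConfig", "TrainConfig", "UNet", "build_model", "dice_loss",
    "dice_loss_grad", "train_step", "predict_volume", "save_checkpoint",
    "load_checkpoint",
]

F32 = np.float32


@dataclass(frozen=True)
class SegModelConfig:
    """Architecture settings for the 2D U-Net."""

    stages: int = 5
    convs_per_stage: int = 2
    base_width: int = 64
    in_channels: int = 1
    out_channels: int = 1
    up_mode: str = "transpose"  # or "nearest"

    def __post_init__(self) -> None:
        if self.stages < 2:
            raise ValueError("a U-Net needs at least 2 stages")
        if self.up_mode not in ("transpose", "nearest"):
            raise ValueError("up_mode must be 'transpose' or 'nearest'")

    def width(self, stage: int) -> int:
        return self.base_width * (2 ** stage)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: Adam with initial learning rate 1e-4, batch
    size 12 and a dice loss; epochs per dataset (e.g. 200 for MRI sources,
    50 for CT sources at clinical scale)."""

    learning_rate: float = 1e-4
    batch_size: int = 12
    epochs: int = 50
    seed: int = 0
    loss: str = "dice"
    binarization_threshold: float = 0.5
    slices_per_epoch: Optional[int] = None

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class _Upsample2x(Layer):
    def forward(self, x, train):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, gy):
        n, c, h, w = gy.shape
        return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def _conv_block(c_in: int, c_out: int, n_convs: int,
                rng: np.random.Generator) -> Sequential:
    layers: list[Layer] = []
    for i in range(n_convs):
        layers += [Conv2d(c_in if i == 0 else c_out, c_out, rng),
                   BatchNorm2d(c_out), ReLU()]
    return Sequential(*layers)


class UNet:
    """Size-preserving encoder-decoder; input sides must be divisible by
    ``2**(stages - 1)``."""

    def __init__(self, config: SegModelConfig, rng: np.random.Generator):
        self.config = config
        s, w = config.stages, config.width
        self.encoders = [
            _conv_block(config.in_channels if i == 0 else w(i - 1), w(i),
                        config.convs_per_stage, rng)
            for i in range(s)
        ]
        self.pools = [MaxPool2d() for _ in range(s - 1)]
        self.ups: list[Layer] = []
        self.decoders = []
        for i in range(s - 2, -1, -1):
            if config.up_mode == "transpose":
                self.ups.append(ConvTranspose2d(w(i + 1), w(i), rng))
            else:
                up_rng = rng
                self.ups.append(Sequential(_Upsample2x(),
                                           Conv2d(w(i + 1), w(i), up_rng)))
            self.decoders.append(
                _conv_block(2 * w(i), w(i), config.convs_per_stage, rng))
        self.head = Conv1x1(config.base_width, config.out_channels, rng)

    # ------------------------------------------------------------- plumbing
    def _modules(self) -> list[Layer]:
        return [*self.encoders, *self.pools, *self.ups, *self.decoders, self.head]

    def parameters(self):
        return [p for m in self._modules() for p in m.parameters()]

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def _leaves(self) -> list[Layer]:
        leaves = []

        def walk(layer):
            if isinstance(layer, Sequential):
                for sub in layer.layers:
                    walk(sub)
            else:
                leaves.append(layer)

        for m in self._modules():
            walk(m)
        return leaves

    _STATE_ATTRS = ("weight", "bias", "gamma", "beta",
                    "running_mean", "running_var")

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, leaf in enumerate(self._leaves()):
            for attr in self._STATE_ATTRS:
                value = getattr(leaf, attr, None)
                if value is not None:
                    state[f"{i}.{attr}"] = value
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, leaf in enumerate(self._leaves()):
            for attr in self._STATE_ATTRS:
                value = getattr(leaf, attr, None)
                if value is not None:
                    setattr(leaf, attr, state[f"{i}.{attr}"].copy())

    # -------------------------------------------------------------- compute
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, H, W) input, "
                f"got {x.shape}"
            )
        factor = 2 ** (self.config.stages - 1)
        if x.shape[2] % factor or x.shape[3] % factor:
            raise ValueError(
                f"input sides {x.shape[2:]} must be divisible by {factor} "
                f"for a {self.config.stages}-stage network"
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=F32)
        skips = []
        for encoder, pool in zip(self.encoders[:-1], self.pools):
            x = encoder.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.encoders[-1].forward(x, train)
        self._skip_widths = []
        for up, decoder, skip in zip(self.ups, self.decoders, reversed(skips)):
            x = up.forward(x, train)
            self._skip_widths.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = decoder.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, gy: np.ndarray) -> None:
        gy = self.head.backward(gy.astype(F32))
        gskips = []
        for up, decoder, width in zip(reversed(self.ups), reversed(self.decoders),
                                      reversed(self._skip_widths)):
            gcat = decoder.backward(gy)
            gskips.append(gcat[:, :width])
            gy = up.backward(np.ascontiguousarray(gcat[:, width:]))
        gy = self.encoders[-1].backward(gy)
        for encoder, pool, gskip in zip(reversed(self.encoders[:-1]),
                                        reversed(self.pools), reversed(gskips)):
            gy = pool.backward(gy) + gskip
            gy = encoder.backward(gy)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode forward pass to sigmoid probabilities."""
        return sigmoid(self.forward(x, train=False))


def build_model(config: SegModelConfig, seed: int = 0) -> UNet:
    """Construct a U-Net with seeded weight initialization."""
    return UNet(config, np.random.default_rng(seed))


# ------------------------------------------------------------------- loss

def dice_loss(pred: np.ndarray, target: np.ndarray,
              eps: float = 1e-6) -> float:
    """Soft dice loss ``1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps)``
    computed over the whole batch."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    intersection = float((pred * target).sum())
    total = float(pred.sum() + target.sum())
    return 1.0 - (2.0 * intersection + eps) / (total + eps)


def dice_loss_grad(pred: np.ndarray, target: np.ndarray,
                   eps: float = 1e-6) -> tuple[float, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    intersection = float((pred * target).sum())
    total = float(pred.sum() + target.sum())
    loss = 1.0 - (2.0 * intersection + eps) / (total + eps)
    denom = (total + eps) ** 2
    grad = -(2.0 * target * (total + eps) - (2.0 * intersection + eps)) / denom
    return loss, grad


def train_step(model: UNet, optimizer: Adam, images: np.ndarray,
               masks: np.ndarray) -> float:
    """One forward/backward/update step; returns the batch dice loss."""
    logits = model.forward(images.astype(F32), train=True)
    probs = sigmoid(logits)
    loss, dprobs = dice_loss_grad(probs, masks)
    if not np.isfinite(loss):
        raise RuntimeError("non-finite dice loss; training diverged")
    dlogits = (dprobs * probs * (1.0 - probs)).astype(F32)
    optimizer.zero_grad()
    model.backward(dlogits)
    optimizer.step()
    return loss


# --------------------------------------------------------------- inference

def _to_batches(voxels: np.ndarray, in_channels: int) -> np.ndarray:
    if voxels.ndim == 3:
        arr = voxels[:, None]
    elif voxels.ndim == 4:
        arr = voxels.transpose(0, 3, 1, 2)
    else:
        raise ValueError(f"expected (D, H, W) or (D, H, W, C), got {voxels.shape}")
    if arr.shape[1] != in_channels:
        raise ValueError(
            f"volume has {arr.shape[1]} channel(s) but the model expects "
            f"{in_channels}"
        )
    return np.ascontiguousarray(arr, dtype=F32)


def predict_volume(model: UNet, volume, threshold: float = 0.5,
                   batch_size: int = 12) -> MaskVolume:
    """Segment a preprocessed volume slice by slice into a 3D binary mask.

    ``volume`` is a :class:`GrayVolume` (grayscale) or an array of shape
    (D, H, W) or (D, H, W, 3) — the latter for colormapped input, which must
    already carry the fixed evaluation colormap when the strategy uses one.
    """
    patient_id = getattr(volume, "patient_id", "")
    voxels = volume.voxels if isinstance(volume, GrayVolume) else np.asarray(volume)
    batches = _to_batches(voxels, model.config.in_channels)
    masks = []
    for start in range(0, batches.shape[0], batch_size):
        probs = model.predict_proba(batches[start:start + batch_size])
        masks.append((probs[:, 0] > threshold).astype(np.uint8))
    return MaskVolume(voxels=np.concatenate(masks), patient_id=patient_id)


# -------------------------------------------------------------- checkpoint

def save_checkpoint(path: str | Path, model: UNet,
                    train_config: TrainConfig | None = None,
                    extra: dict | None = None) -> None:
    """Write weights plus model/training configuration to an ``.npz``."""
    meta = {
        "model_config": asdict(model.config),
        "train_config": asdict(train_config) if train_config else None,
        "extra": extra or {},
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.state_arrays())


def load_checkpoint(path: str | Path) -> tuple[UNet, dict]:
    """Rebuild a model from a checkpoint; returns (model, metadata)."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = build_model(SegModelConfig(**meta["model_config"]))
    model.load_state_arrays(state)
    return model, meta
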