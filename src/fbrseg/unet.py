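"""U-Net variant: architecture, learning-rate schedule, training and inference.

The network is the classic encoder/decoder with skip concatenation, with two
departures that matter for small microscopy datasets: batch normalization
between every convolution and its ReLU (prevents early loss saturation), and
learnable transposed convolutions for upsampling.  Filter counts double per
encoding level starting from ``base_filters``; with base 16 and depth 5 the
bottleneck holds 256 filters.  Training minimizes a task-specific objective
(class-balanced Dice or boundary-weighted BCE) plus an L2 penalty
``(lambda/2)||w||^2`` on convolution kernels, under Adam with a sigmoid-like
decaying base learning rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .augment import SplitDataset
from .losses import (
    ClassBalance,
    custom_metric,
    iou,
    multiclass_dice_grad,
    multiclass_dice_loss,
    weighted_bce_grad,
    weighted_bce_loss,
)


@dataclass
class UNetConfig:
    base_filters: int = 16
    depth: int = 5
    n_classes: int = 3
    input_size: int = 512
    in_channels: int = 1
    l2_lambda: float = 0.01
    kernel_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_filters < 1 or self.depth < 1:
            raise ValueError("base_filters and depth must be >= 1")


@dataclass
class LRSchedule:
    """Sigmoid-like decay from lr0 to lr_inf, saturating around epoch e_inf."""

    lr0: float = 0.001
    lr_inf: float = 0.0001
    e0: int = 0
    e_inf: int = 200

    def __post_init__(self) -> None:
        if not self.lr0 > self.lr_inf > 0:
            raise ValueError("require lr0 > lr_inf > 0")
        if self.e_inf <= self.e0:
            raise ValueError("require e_inf > e0")


@dataclass
class TrainingConfig:
    epochs: int = 300
    batch_size: int = 8
    seed: int = 0


def lr_at_epoch(epoch: int, sched: LRSchedule = LRSchedule()) -> float:
    """Base learning rate at a given epoch.

    ``lr(E) = (lr0 - lr_inf) / (1 + exp(s(E))) + lr_inf`` with
    ``s(E) = (E - span/2) / (span/10)`` and ``span = e_inf - e0``; the
    midpoint epoch yields the mean of the two extremes.
    """
    span = sched.e_inf - sched.e0
    s = (epoch - span / 2.0) / (span / 10.0)
    return (sched.lr0 - sched.lr_inf) / (1.0 + np.exp(s)) + sched.lr_inf


class _ConvBlock(nn.Sequential):
    """conv -> BN -> ReLU, twice."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator) -> None:
        super().__init__(
            nn.Conv2D(c_in, c_out, k, rng), nn.BatchNorm2D(c_out), nn.ReLU(),
            nn.Conv2D(c_out, c_out, k, rng), nn.BatchNorm2D(c_out), nn.ReLU(),
        )


class UNet:
    """Fully convolutional segmentation network; output size equals input size."""

    def __init__(self, cfg: UNetConfig) -> None:
        step = 2 ** (cfg.depth - 1)
        if cfg.input_size % step != 0:
            valid = [cfg.input_size // step * step, (cfg.input_size // step + 1) * step]
            raise ValueError(
                f"input_size must be divisible by {step}; nearest valid sizes: {valid}"
            )
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        b, d, k = cfg.base_filters, cfg.depth, cfg.kernel_size

        self.enc: list[_ConvBlock] = []
        c_in = cfg.in_channels
        for level in range(d):
            c_out = b * 2**level
            self.enc.append(_ConvBlock(c_in, c_out, k, rng))
            c_in = c_out
        self.pools = [nn.MaxPool2x2() for _ in range(d - 1)]

        self.ups: list[nn.TransposedConv2x2] = []
        self.dec: list[_ConvBlock] = []
        for level in range(d - 2, -1, -1):
            c_skip = b * 2**level
            self.ups.append(nn.TransposedConv2x2(c_skip * 2, c_skip, rng))
            self.dec.append(_ConvBlock(c_skip * 2, c_skip, k, rng))

        # output head: 1x1 conv, no batch norm, softmax (>=2 classes) or sigmoid
        self.head_conv = nn.Conv2D(b, cfg.n_classes, 1, rng)
        self.head_act = nn.Softmax() if cfg.n_classes >= 2 else nn.Sigmoid()

    # -- graph traversal ----------------------------------------------------

    def _layers(self) -> list[nn.Layer]:
        flat: list[nn.Layer] = []
        for block in self.enc + self.dec:
            flat.extend(block.layers)
        flat.extend(self.ups)
        flat.append(self.head_conv)
        return flat

    def parameters(self) -> list[tuple[nn.Layer, str]]:
        return [(layer, k) for layer in self._layers() for k in layer.params]

    def conv_kernels(self) -> list[tuple[nn.Layer, str]]:
        """Convolution kernels subject to L2 (not biases, not batch norm)."""
        return [
            (layer, "w")
            for layer in self._layers()
            if isinstance(layer, (nn.Conv2D, nn.TransposedConv2x2))
        ]

    def n_parameters(self) -> int:
        return sum(layer.params[k].size for layer, k in self.parameters())

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        skips = []
        for i, block in enumerate(self.enc):
            x = block.forward(x, training)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x, training)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, training)
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, training)
        x = self.head_conv.forward(x, training)
        return self.head_act.forward(x, training)

    def backward(self, gout: np.ndarray) -> None:
        g = self.head_act.backward(gout.astype(nn.F32))
        g = self.head_conv.backward(g)
        skip_grads: list[np.ndarray] = []
        for up, dec in zip(reversed(self.ups), reversed(self.dec)):
            g = dec.backward(g)
            c = g.shape[1] // 2
            skip_grads.append(g[:, :c])
            g = up.backward(g[:, c:])
        for i in range(len(self.enc) - 1, -1, -1):
            if i < len(self.pools):
                g = self.pools[i].backward(g)
                g = g + skip_grads[i]
            g = self.enc[i].backward(g)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Weights as .npz next to a JSON sidecar holding the configuration."""
        path = Path(path)
        arrays = {}
        for idx, (layer, k) in enumerate(self.parameters()):
            arrays[f"p{idx}_{k}"] = layer.params[k]
        for idx, layer in enumerate(self._layers()):
            if isinstance(layer, nn.BatchNorm2D):
                arrays[f"bn{idx}_mean"] = layer.running_mean
                arrays[f"bn{idx}_var"] = layer.running_var
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.cfg), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        path = Path(path)
        cfg = UNetConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(cfg)
        data = np.load(path.with_suffix(".npz"))
        for idx, (layer, k) in enumerate(model.parameters()):
            layer.params[k] = data[f"p{idx}_{k}"]
        for idx, layer in enumerate(model._layers()):
            if isinstance(layer, nn.BatchNorm2D):
                layer.running_mean = data[f"bn{idx}_mean"]
                layer.running_var = data[f"bn{idx}_var"]
        return model


def build_unet(cfg: UNetConfig) -> UNet:
    return UNet(cfg)


# ---------------------------------------------------------------------------
# objectives


class DiceObjective:
    """Class-balanced multiclass Dice; targets are one-hot (N, C, H, W)."""

    def __init__(self, balance: ClassBalance) -> None:
        self.balance = balance

    def value(self, y: np.ndarray, p: np.ndarray, w=None) -> float:
        return multiclass_dice_loss(y, p, self.balance)

    def grad(self, y: np.ndarray, p: np.ndarray, w=None) -> np.ndarray:
        return multiclass_dice_grad(y, p, self.balance)


class WeightedBCEObjective:
    """Boundary-weighted BCE; targets/weights are (N, H, W), predictions (N, 1, H, W)."""

    def value(self, y: np.ndarray, p: np.ndarray, w: np.ndarray) -> float:
        return weighted_bce_loss(y, p[:, 0], w)

    def grad(self, y: np.ndarray, p: np.ndarray, w: np.ndarray) -> np.ndarray:
        return weighted_bce_grad(y, p[:, 0], w)[:, None]


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)       # regularized
    train_base_loss: list[float] = field(default_factory=list)  # data term only
    val_metric: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)


def _stack_batch(samples: list[tuple], n_classes: int) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Assemble (x, y, w) mini-batch arrays from (image, mask[, weight]) tuples."""
    imgs = np.stack([np.asarray(s[0], dtype=nn.F32) for s in samples])[:, None]
    masks = np.stack([np.asarray(s[1]) for s in samples])
    if n_classes >= 2:
        y = np.stack(
            [np.stack([(m == c) for c in range(n_classes)]).astype(np.float64) for m in masks]
        )
    else:
        y = (masks > 0).astype(np.float64)
    w = None
    if len(samples[0]) > 2:
        w = np.stack([np.asarray(s[2], dtype=np.float64) for s in samples])
    return imgs, y, w


def evaluate_iou(model: UNet, samples: list[tuple]) -> float:
    """Mean foreground IoU (binary head) or mean per-class IoU (softmax head)."""
    vals = []
    for s in samples:
        p = model.forward(np.asarray(s[0], dtype=nn.F32)[None, None])[0]
        truth = np.asarray(s[1])
        if model.cfg.n_classes >= 2:
            pred = p.argmax(axis=0)
            vals.append(np.mean([iou(truth == c, pred == c) for c in range(model.cfg.n_classes)]))
        else:
            vals.append(iou(truth > 0, p[0] > 0.5))
    return float(np.mean(vals))


def train(
    model: UNet,
    data: SplitDataset,
    objective,
    tcfg: TrainingConfig,
    sched: LRSchedule | None = None,
) -> TrainingHistory:
    """Mini-batch Adam training with the sigmoid-decay learning rate.

    Records per-epoch mean training loss (with and without the L2 term) and
    the validation IoU.  Raises on a non-finite loss.
    """
    if not data.train:
        raise ValueError("empty training set")
    sched = sched or LRSchedule()
    rng = np.random.default_rng(tcfg.seed)
    opt = nn.Adam(model.parameters())
    kernels = model.conv_kernels()
    lam = model.cfg.l2_lambda
    hist = TrainingHistory()

    for epoch in range(tcfg.epochs):
        lr = lr_at_epoch(epoch, sched)
        order = rng.permutation(len(data.train))
        base_losses, losses = [], []
        for start in range(0, len(order), tcfg.batch_size):
            batch = [data.train[i] for i in order[start : start + tcfg.batch_size]]
            x, y, w = _stack_batch(batch, model.cfg.n_classes)
            p = model.forward(x, training=True)
            base = objective.value(y, p, w)
            if not np.isfinite(base):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            reg = 0.5 * lam * sum(float((layer.params[k] ** 2).sum()) for layer, k in kernels)
            model.backward(objective.grad(y, p, w))
            if lam > 0:
                for layer, k in kernels:
                    layer.grads[k] = layer.grads[k] + lam * layer.params[k]
            opt.step(lr)
            base_losses.append(base)
            losses.append(base + reg)
        hist.train_base_loss.append(float(np.mean(base_losses)))
        hist.train_loss.append(float(np.mean(losses)))
        hist.lr.append(float(lr))
        hist.val_metric.append(evaluate_iou(model, data.val) if data.val else float("nan"))
    return hist


def predict(model: UNet, pixels: np.ndarray) -> np.ndarray:
    """Per-pixel class probabilities (C, H, W) for one preprocessed image."""
    x = np.asarray(pixels, dtype=nn.F32)
    if x.ndim != 2:
        raise ValueError("predict expects a single 2D image")
    if x.shape[0] != model.cfg.input_size or x.shape[1] != model.cfg.input_size:
        raise ValueError(
            f"image shape {x.shape} does not match model input size {model.cfg.input_size}"
        )
    return model.forward(x[None, None])[0]


def hard_mask(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Argmax (multiclass) or 0.5-threshold (binary) hard labels from probabilities."""
    if prob.shape[0] == 1:
        return (prob[0] > threshold).astype(np.int64)
    return prob.argmax(axis=0).astype(np.int64)
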