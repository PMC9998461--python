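"""Epithelium segmentation: U-Net trained with the BCE-Dice loss.

The loss is the sum of a pixel-averaged binary cross-entropy and a soft
Dice loss computed on whole-image sums,

    L_s = BCE + DiceLoss,
    DiceLoss = 1 - (2 * sum(y * p) + lambda) / (sum(y) + sum(p) + lambda),

with the smoothing factor lambda (default 1) rescuing the empty-mask
case. Predictions are clamped to [eps, 1-eps] before the log terms, which
are otherwise unbounded. Input variants: RGB (3 channels), grayscale or
the HSV saturation channel (1 channel each).
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path

import numpy as np

from . import nn
from .slide_io import FragmentCrop, unwarp_mask_to_level0

__all__ = [
    "SegConfig",
    "SegLossTerms",
    "SegModel",
    "bce_dice_loss",
    "to_input_channels",
    "train_segmenter",
    "predict_probability_map",
    "predict_mask",
]

_EPS = 1e-7

_GRAY_WEIGHTS = np.array([0.2125, 0.7154, 0.0721], dtype=np.float32)


@dataclasses.dataclass
class SegConfig:
    """Training configuration; defaults are the full-scale settings
    (250 epochs, lr 1e-4, batches of 4, depth-4/64-filter U-Net), while
    tests run the depth-2/8-filter desk scale."""

    input_mode: str = "rgb"
    depth: int = 4
    base_filters: int = 64
    lambda_smooth: float = 1.0
    learning_rate: float = 1e-4
    batch_size: int = 4
    epochs: int = 250
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.input_mode not in ("rgb", "gray", "saturation"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if self.lambda_smooth <= 0:
            raise ValueError("lambda_smooth must be > 0")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")

    @property
    def in_channels(self) -> int:
        return 3 if self.input_mode == "rgb" else 1


@dataclasses.dataclass(frozen=True)
class SegLossTerms:
    bce: float
    dice_loss: float

    @property
    def total(self) -> float:
        return self.bce + self.dice_loss


def bce_dice_loss(pred, target, lambda_smooth: float = 1.0) -> SegLossTerms:
    """BCE-Dice loss of a probability map against a binary target."""
    p = np.asarray(pred, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("predictions must be probabilities in [0, 1]")
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    bce = float(-(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)).mean())
    inter = float((y * p).sum())
    dice = 1.0 - (2.0 * inter + lambda_smooth) / (y.sum() + p.sum() + lambda_smooth)
    return SegLossTerms(bce=bce, dice_loss=float(dice))


def _loss_and_logit_grad(logits: np.ndarray, targets: np.ndarray,
                         lambda_smooth: float) -> tuple[float, float, np.ndarray]:
    """Per-image BCE-Dice averaged over the batch, with d(loss)/d(logits)."""
    n = logits.shape[0]
    probs = nn.sigmoid(logits)
    dz = np.zeros_like(logits)
    bce_sum = 0.0
    dice_sum = 0.0
    for i in range(n):
        p = probs[i]
        y = targets[i]
        n_pix = p.size
        pc = np.clip(p, _EPS, 1.0 - _EPS)
        bce_sum += float(-(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)).mean())
        denom = float(y.sum() + p.sum()) + lambda_smooth
        inter = float((y * p).sum())
        dice_sum += 1.0 - (2.0 * inter + lambda_smooth) / denom
        # d(BCE)/dz = (p - y) / n_pix ; d(Dice)/dp then chain through sigmoid
        ddice_dp = -(2.0 * y * denom - (2.0 * inter + lambda_smooth)) / denom**2
        dz[i] = (p - y) / n_pix + ddice_dp * p * (1.0 - p)
    return bce_sum / n, dice_sum / n, dz / n


def to_input_channels(crop, mode: str) -> np.ndarray:
    """Convert an RGB crop to the model input tensor (C, H, W) in [0, 1]."""
    img = crop.image if isinstance(crop, FragmentCrop) else crop
    img = np.asarray(img, dtype=np.float32) / 255.0
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if mode == "rgb":
        return img.transpose(2, 0, 1).copy()
    if mode == "gray":
        return (img @ _GRAY_WEIGHTS)[None]
    if mode == "saturation":
        mx = img.max(axis=2)
        mn = img.min(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, _EPS), 0.0)
        return sat[None].astype(np.float32)
    raise ValueError(f"unknown input mode {mode!r}")


class SegModel:
    """A trained U-Net plus its input mode and decision threshold."""

    def __init__(self, net: nn.UNet, config: SegConfig):
        self.net = net
        self.config = config

    def predict_proba(self, crop) -> np.ndarray:
        x = to_input_channels(crop, self.config.input_mode)[None]
        logits = self.net.forward(x)
        return nn.sigmoid(logits[0, 0])

    def save(self, path) -> None:
        nn.save_model(path, self.net, "unet", meta=dataclasses.asdict(self.config))

    @classmethod
    def load(cls, path) -> "SegModel":
        net, sidecar = nn.load_model(path)
        return cls(net, SegConfig(**sidecar["meta"]))

    def digest(self) -> str:
        return nn.model_digest(self.net)


def _stack_inputs(pairs, mode: str) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([to_input_channels(crop, mode) for crop, _ in pairs])
    ys = np.stack([np.asarray(mask, dtype=np.float32) for _, mask in pairs])[:, None]
    return xs, ys


def train_segmenter(train, val, config: SegConfig, log_path=None) -> SegModel:
    """Train a U-Net and return the minimum-validation-loss checkpoint.

    ``train``/``val`` are lists of (FragmentCrop, binary mask) pairs with
    masks aligned to the crop pixel grid. Fully seeded: two runs with the
    same data and config produce identical checkpoints.
    """
    if not train or not val:
        raise ValueError("train and val sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    net = nn.UNet(in_channels=config.in_channels, depth=config.depth,
                  base_filters=config.base_filters, rng=rng)
    opt = nn.Adam(net.params(), lr=config.learning_rate)
    x_train, y_train = _stack_inputs(train, config.input_mode)
    x_val, y_val = _stack_inputs(val, config.input_mode)

    best_val = np.inf
    best_params = nn.checkpoint.clone_params(net)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        tr_bce = tr_dice = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = net.forward(x_train[idx])
            bce, dice, dz = _loss_and_logit_grad(logits, y_train[idx, 0][:, None],
                                                 config.lambda_smooth)
            if not np.isfinite(bce + dice):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            net.backward(dz.astype(np.float32))
            opt.step()
            tr_bce += bce
            tr_dice += dice
            n_batches += 1
        val_bce = val_dice = 0.0
        for i in range(len(val)):
            probs = nn.sigmoid(net.forward(x_val[i:i + 1])[0, 0])
            terms = bce_dice_loss(probs, y_val[i, 0], config.lambda_smooth)
            val_bce += terms.bce
            val_dice += terms.dice_loss
        val_loss = (val_bce + val_dice) / len(val)
        history.append({"epoch": epoch, "train_bce": tr_bce / n_batches,
                        "train_dice_loss": tr_dice / n_batches,
                        "train_loss": (tr_bce + tr_dice) / n_batches,
                        "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_params = nn.checkpoint.clone_params(net)

    nn.checkpoint.set_params(net, best_params)
    model = SegModel(net, config)
    model.history = history
    model.best_val_loss = float(best_val)
    if log_path is not None:
        log_path = Path(log_path)
        log_path.parent.mkdir(parents=True, exist_ok=True)
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
            writer.writeheader()
            writer.writerows(history)
    return model


def predict_probability_map(model: SegModel, crop) -> np.ndarray:
    return model.predict_proba(crop)


def predict_mask(model: SegModel, crop, threshold: float | None = None,
                 canvas_shape: tuple[int, int] | None = None):
    """Threshold the predicted probability map.

    Returns the crop-space mask; when ``canvas_shape`` is given, also the
    mask mapped back to level-0 through the crop transform.
    """
    thr = model.config.threshold if threshold is None else threshold
    probs = model.predict_proba(crop)
    mask = np.asarray(probs > thr, dtype=bool)  # strict: p = 0.5 at t = 0.5 is background
    if canvas_shape is None:
        return mask
    return mask, unwarp_mask_to_level0(crop, mask, canvas_shape)
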