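"""Segmentation network construction, training, inference, and validated
threshold selection.

Model input contract: single-channel 2D slices of windowed grey values in
[0, 255] (as produced by :func:`mvseg.preprocess.apply_window`); they are
scaled to [0, 1] internally.  The network outputs a per-pixel probability map
of the same shape.

Training follows the conventional recipe for this family of pipelines: binary
cross-entropy loss, Adam, mini-batches sampled randomly from all training
slices (empty-mask slices included), on-the-fly rotation/shift/zoom
augmentation, and early stopping on validation loss with the best-epoch
weights restored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metrics import dice
from .nn import Adam, UNet2D, bce_with_logits, sigmoid
from .preprocess import AugmentParams, augment_pair
from .views import ViewStack
from .volume import Volume

logger = logging.getLogger(__name__)

INPUT_SCALE = 255.0

DEFAULT_THRESHOLD_GRID = tuple(round(0.05 * k, 2) for k in range(1, 20))


@dataclass(frozen=True)
class SegModelConfig:
    """Architecture hyperparameters of one 2D U-Net."""

    depth: int = 2
    base_filters: int = 8
    input_shape: tuple[int, int] = (128, 128)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_filters < 1:
            raise ValueError("depth and base_filters must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow the pipeline's reference settings: binary cross-entropy,
    Adam at 1e-4, patience 15; batch size 20 for the coarse stage and 10 for
    the single-view stages.  ``steps_per_epoch`` caps the optimizer steps per
    epoch (None = one full pass over the training slices).
    """

    loss: str = "binary_cross_entropy"
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 10
    patience: int = 15
    max_epochs: int = 100
    steps_per_epoch: int | None = None
    augment: AugmentParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss != "binary_cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.patience < 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("patience >= 0, batch_size >= 1, max_epochs >= 1")


@dataclass(frozen=True)
class SliceSet:
    """A set of training/validation slices and their binary masks."""

    images: np.ndarray  # (n, h, w), windowed grey values in [0, 255]
    masks: np.ndarray  # (n, h, w), values in {0, 1}

    def __post_init__(self) -> None:
        if self.images.shape != self.masks.shape or self.images.ndim != 3:
            raise ValueError("images and masks must be matching (n, h, w) arrays")

    def __len__(self) -> int:
        return self.images.shape[0]


@dataclass
class TrainedModel:
    """A (possibly still untrained) network plus its training history."""

    config: SegModelConfig
    net: UNet2D
    history: list[dict] = field(default_factory=list)

    def predict_slices(self, slices: np.ndarray, batch: int = 32) -> np.ndarray:
        """Per-slice probability maps for an (n, h, w) stack."""
        slices = np.asarray(slices)
        if slices.shape[1:] != self.config.input_shape:
            raise ValueError(
                f"slice shape {slices.shape[1:]} does not match model input "
                f"{self.config.input_shape}"
            )
        x = (slices.astype(np.float32) / INPUT_SCALE)[..., None]
        out = np.empty(slices.shape, dtype=np.float32)
        for i in range(0, len(slices), batch):
            logits = self.net.forward(x[i : i + batch])
            out[i : i + batch] = sigmoid(logits)[..., 0]
        return out


def build_model(cfg: SegModelConfig) -> TrainedModel:
    """Instantiate a U-Net with deterministic seeded initialization."""
    h, w = cfg.input_shape
    if h % (1 << cfg.depth) or w % (1 << cfg.depth):
        raise ValueError(
            f"input shape {cfg.input_shape} must be divisible by 2^depth "
            f"= {1 << cfg.depth}"
        )
    net = UNet2D(cfg.depth, cfg.base_filters, cfg.input_shape, cfg.seed)
    return TrainedModel(config=cfg, net=net)


def _epoch_loss(model: TrainedModel, s: SliceSet, batch: int = 64) -> float:
    """Mean BCE over a slice set, without augmentation or weight updates."""
    x = (s.images.astype(np.float32) / INPUT_SCALE)[..., None]
    t = s.masks.astype(np.float32)[..., None]
    total = 0.0
    for i in range(0, len(s), batch):
        logits = model.net.forward(x[i : i + batch])
        loss, _ = bce_with_logits(logits, t[i : i + batch])
        total += loss * (min(i + batch, len(s)) - i)
    return total / len(s)


def train(
    model: TrainedModel,
    train_slices: SliceSet,
    val_slices: SliceSet,
    tc: TrainConfig,
) -> TrainedModel:
    """Train in place; returns the model with best-validation weights restored.

    Each epoch draws ``steps_per_epoch`` mini-batches (default: one shuffled
    pass) of ``batch_size`` slices, augments them on the fly, and takes one
    Adam step per batch.  Training stops when the validation loss has not
    improved for ``patience`` consecutive epochs, or at ``max_epochs``.
    """
    if len(train_slices) == 0:
        raise ValueError("training set is empty")
    if len(val_slices) == 0:
        raise ValueError("validation set is empty")
    if train_slices.images.shape[1:] != model.config.input_shape:
        raise ValueError("training slices do not match the model input shape")

    rng = np.random.default_rng(tc.seed)
    opt = Adam(lr=tc.learning_rate)
    n = len(train_slices)
    steps = tc.steps_per_epoch or -(-n // tc.batch_size)

    best_val = np.inf
    best_weights = model.net.get_weights()
    bad_epochs = 0
    model.history = []

    for epoch in range(tc.max_epochs):
        order = rng.permutation(n)
        need = steps * tc.batch_size
        while order.size < need:
            order = np.concatenate([order, rng.permutation(n)])
        train_loss = 0.0
        for s in range(steps):
            idx = order[s * tc.batch_size : (s + 1) * tc.batch_size]
            xb = np.empty((len(idx),) + model.config.input_shape, dtype=np.float32)
            tb = np.empty_like(xb)
            for j, i in enumerate(idx):
                img = train_slices.images[i]
                msk = train_slices.masks[i]
                if tc.augment is not None:
                    img, msk = augment_pair(img, msk, tc.augment, rng=rng)
                xb[j] = img
                tb[j] = msk
            logits = model.net.forward((xb / INPUT_SCALE)[..., None])
            loss, dz = bce_with_logits(logits, tb[..., None])
            model.net.backward(dz)
            opt.step(model.net.params())
            train_loss += loss
        train_loss /= steps
        val_loss = _epoch_loss(model, val_slices)
        model.history.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
        )
        logger.info(
            "epoch %d: train loss %.4f, val loss %.4f", epoch, train_loss, val_loss
        )
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_weights = model.net.get_weights()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > tc.patience:
                logger.info("early stopping at epoch %d", epoch)
                break

    model.net.set_weights(best_weights)
    return model


def predict_stack(model: TrainedModel, stack: ViewStack) -> Volume:
    """Run per-slice inference over a view stack; reassemble to a 3D volume."""
    probs = model.predict_slices(stack.slices)
    return stack.to_volume(np.clip(probs, 0.0, 1.0), role="probability")


def select_threshold(
    prob_volumes: list[Volume],
    gt_masks: list[Volume],
    grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID,
) -> float:
    """Grid value maximizing mean per-case 3D Dice; ties go to the smallest.

    This is the validated-binarization step: one global threshold per model,
    chosen on held-out validation cases.
    """
    if not prob_volumes or len(prob_volumes) != len(gt_masks):
        raise ValueError("need equal, nonempty lists of predictions and masks")
    grid = sorted(float(t) for t in grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    if any(t <= 0 or t >= 1 for t in grid):
        raise ValueError("grid values must lie in (0, 1)")
    for p, g in zip(prob_volumes, gt_masks):
        if p.shape != g.shape:
            raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    best_t, best_score = grid[0], -1.0
    for t in grid:
        score = float(
            np.mean(
                [
                    dice(g, p.with_data((p.data >= t).astype(np.uint8), role="label"))
                    for p, g in zip(prob_volumes, gt_masks)
                ]
            )
        )
        if score > best_score + 1e-12:
            best_score, best_t = score, t
    return best_t


# -- serialization -----------------------------------------------------------


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Save architecture config, weights, and history to an .npz file."""
    path = Path(path)
    cfg = model.config
    meta = {
        "depth": cfg.depth,
        "base_filters": cfg.base_filters,
        "input_shape": list(cfg.input_shape),
        "seed": cfg.seed,
        "history": model.history,
    }
    weights = model.net.get_weights()
    np.savez_compressed(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **{f"w{i}": w for i, w in enumerate(weights)},
    )
    return path


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    cfg = SegModelConfig(
        depth=meta["depth"],
        base_filters=meta["base_filters"],
        input_shape=tuple(meta["input_shape"]),
        seed=meta["seed"],
    )
    model = build_model(cfg)
    model.net.set_weights(weights)
    model.history = meta["history"]
    return model
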