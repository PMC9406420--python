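"""Training with Adam + IoU loss, validation-loss early stopping, evaluation.

The optimizer and its settings follow the published protocol: Adam at
learning rate 1e-4, batch size 4, soft-IoU loss.  After every epoch the mean
validation loss feeds an early-stop controller that tracks the best score
seen so far and a counter of consecutive non-improving epochs; once the
counter exceeds the patience (default 20), training halts and the weights
from the best epoch are restored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .metrics import Metrics, PixelConfusion, compute_metrics, normalized_confusion_report, pixel_confusion
from .model import ConnectedSegNets, save_checkpoint
from .nn import Adam, backward
from .nn import functional as F
from .nn.tensor import no_grad

__all__ = ["TrainConfig", "EarlyStopState", "early_stop_update", "train",
           "evaluate", "reestimate_bn_stats"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters and the early-stop patience."""

    learning_rate: float = 1e-4
    batch_size: int = 4
    max_epochs: int = 200
    patience: int = 20  # consecutive non-improving epochs tolerated
    seed: int = 0
    eval_threshold: float = 0.5
    #: optional convergence target: stop once validation Dice reaches it
    target_val_dice: float | None = None

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.patience < 0:
            raise ConfigError("patience must be >= 0")
        if self.max_epochs < 1:
            raise ConfigError("max_epochs must be >= 1")


@dataclass(frozen=True)
class EarlyStopState:
    """Validation-loss tracker: best score, consecutive non-improving count, stop flag."""

    best_val_loss: float = math.inf
    non_improving: int = 0
    patience: int = 20
    early_stop: bool = False


def early_stop_update(state: EarlyStopState, latest_val_loss: float) -> EarlyStopState:
    """Fold one epoch's validation loss into the tracker.

    A strict improvement resets the counter and records the new best;
    anything else (including a tie) increments the counter, and once it
    exceeds the patience the stop flag is raised.  The best score never
    increases.
    """
    if not math.isfinite(latest_val_loss):
        raise DataError(f"validation loss is not finite: {latest_val_loss}")
    if latest_val_loss < state.best_val_loss:
        return replace(state, best_val_loss=latest_val_loss, non_improving=0)
    count = state.non_improving + 1
    return replace(state, non_improving=count, early_stop=count > state.patience)


def _as_xy(dataset) -> tuple[np.ndarray, np.ndarray]:
    images, masks = dataset
    images = np.asarray(images, dtype=np.float32)
    masks = np.asarray(masks, dtype=np.float32)
    if images.ndim == 3:
        images = images[..., None]
    if masks.ndim == 3:
        masks = masks[..., None]
    if images.shape != masks.shape or len(images) == 0:
        raise ConfigError(f"dataset images {images.shape} and masks {masks.shape} must match and be nonempty")
    return images, masks


def _batched_loss_and_confusion(model, images, masks, batch_size, threshold):
    losses, conf = [], PixelConfusion(0, 0, 0, 0)
    correct = 0
    with no_grad():
        for i in range(0, len(images), batch_size):
            xb, yb = images[i:i + batch_size], masks[i:i + batch_size]
            pred = model.forward(xb)
            losses.append(float(F.soft_iou_loss(pred, yb).data) * len(xb))
            pb = (pred.data >= threshold).astype(np.uint8)
            conf = conf + pixel_confusion(pb, yb.astype(np.uint8))
            correct += int(np.count_nonzero(pb == yb))
    return sum(losses) / len(images), conf, correct / masks.size


def train(model: ConnectedSegNets, train_set, val_set, config: TrainConfig = TrainConfig(),
          run_dir: str | Path | None = None, verbose: bool = False):
    """Train ``model``; returns (history DataFrame, best state_dict).

    ``train_set``/``val_set`` are ``(images, masks)`` pairs of N x H x W
    arrays.  Per epoch: seeded shuffle, mini-batch Adam steps on the soft-IoU
    loss, then validation loss/Dice/IoU (threshold ``eval_threshold``) and one
    early-stop update.  The best-validation weights are restored at the end
    and written to ``run_dir/checkpoint_best.npz`` when a run directory is
    given; a NaN training loss aborts with the last good weights kept.
    """
    config.validate()
    xtr, ytr = _as_xy(train_set)
    xva, yva = _as_xy(val_set)
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    stopper = EarlyStopState(patience=config.patience)
    best_state = model.state_dict()
    history: list[dict] = []
    run_dir = Path(run_dir) if run_dir is not None else None
    if run_dir is not None:
        run_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(1, config.max_epochs + 1):
        model.train()
        order = rng.permutation(len(xtr))
        epoch_loss = 0.0
        for i in range(0, len(order), config.batch_size):
            sel = order[i:i + config.batch_size]
            pred = model.forward(xtr[sel])
            loss = F.soft_iou_loss(pred, ytr[sel])
            if not np.isfinite(loss.data):
                raise DataError(f"training loss diverged (NaN) at epoch {epoch}")
            optimizer.zero_grad()
            backward(loss)
            optimizer.step()
            epoch_loss += float(loss.data) * len(sel)
        epoch_loss /= len(xtr)

        model.eval()
        val_loss, conf, pix_acc = _batched_loss_and_confusion(
            model, xva, yva, config.batch_size, config.eval_threshold)
        m = compute_metrics(conf)
        prev_best = stopper.best_val_loss
        stopper = early_stop_update(stopper, val_loss)
        if val_loss < prev_best:
            best_state = model.state_dict()
            if run_dir is not None:
                save_checkpoint(model, run_dir / "checkpoint_best.npz")
        history.append({
            "epoch": epoch, "train_loss": epoch_loss, "val_loss": val_loss,
            "val_dice": m.dice, "val_iou": m.iou, "val_pixel_acc": pix_acc,
            "learning_rate": config.learning_rate, "batch_size": config.batch_size,
        })
        if verbose:
            print(f"epoch {epoch:3d}  train_loss {epoch_loss:.4f}  val_loss {val_loss:.4f}"
                  f"  val_dice {m.dice:.4f}  val_iou {m.iou:.4f}")
        if stopper.early_stop:
            break
        if config.target_val_dice is not None and m.dice >= config.target_val_dice:
            best_state = model.state_dict()  # convergence target met: keep these weights
            break

    model.load_state_dict(best_state)
    hist = pd.DataFrame(history)
    if run_dir is not None:
        hist.to_csv(run_dir / "history.csv", index=False, lineterminator="\n")
    return hist, best_state


def reestimate_bn_stats(model: ConnectedSegNets, images: np.ndarray,
                        batch_size: int = 4) -> None:
    """Refresh batch-norm running statistics with the final weights.

    With small batches the exponential running estimates lag behind the
    weights they are paired with; one sweep over the (training) images in
    training mode, without gradient steps, re-centers them.  Standard
    inference calibration for small-batch batch-norm models.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[..., None]
    model.train()
    with no_grad():
        for i in range(0, len(images), batch_size):
            model.forward(images[i:i + batch_size])
    model.eval()


def evaluate(model: ConnectedSegNets, test_set, threshold: float = 0.5,
             batch_size: int = 4):
    """Per-sample and pixel-pooled metrics plus the normalized confusion table.

    Returns a dict with ``per_sample`` (DataFrame), ``aggregate`` (Metrics of
    the summed confusion), ``confusion`` (PixelConfusion) and
    ``normalized_confusion`` (2x2 percentage DataFrame).
    """
    images, masks = _as_xy(test_set)
    model.eval()
    rows = []
    pooled = PixelConfusion(0, 0, 0, 0)
    preds = model.predict(images[..., 0], threshold=threshold, batch_size=batch_size)
    for i in range(len(images)):
        conf = pixel_confusion(preds[i], masks[i, ..., 0].astype(np.uint8))
        pooled = pooled + conf
        m = compute_metrics(conf)
        rows.append({"index": i, **m.__dict__})
    aggregate = compute_metrics(pooled)
    try:
        normalized = normalized_confusion_report(pooled)
    except DataError:
        normalized = None
    return {
        "per_sample": pd.DataFrame(rows),
        "aggregate": aggregate,
        "confusion": pooled,
        "normalized_confusion": normalized,
    }
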