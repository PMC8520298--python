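"""Training protocol: Adam, LR-on-plateau, early stopping, evaluation.

The optimizer minimizes the compound loss (0.5·BCE + 1.0·Dice by
default). After every epoch the validation loss is monitored: if it has
not improved (decrease of at least ``min_delta``) for ``lr_patience``
epochs the learning rate is halved, and if it has not improved for
``early_stop_patience`` epochs training stops early; the weights that
were best on validation are restored at the end.

Evaluation binarizes predictions at 0.5 and computes per-case
DSC/IOU/precision/recall, aggregated as mean ± standard deviation.
Per-case metrics pool all slices of a case ("per-volume"); a per-slice
mode averages slice-level metrics within the case instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor
from .losses import LossWeights, binarize, total_loss
from .metrics import MetricsReport, segmentation_metrics
from .nn import Adam
from .preprocessing import tta_predict

__all__ = ["TrainConfig", "train", "evaluate", "TrainingDiverged"]


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite."""


@dataclass
class TrainConfig:
    lr: float = 0.001
    batch_size: int = 6
    max_epochs: int = 300
    lr_patience: int = 8
    lr_factor: float = 0.5
    early_stop_patience: int = 20
    min_delta: float = 1e-4
    loss_weights: LossWeights = field(default_factory=LossWeights)
    rng_seed: int = 0
    shuffle: bool = True

    def validate(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.lr_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patiences must be >= 1")
        if not 0.0 < self.lr_factor < 1.0:
            raise ValueError("lr_factor must be in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


def _as_batch(images: np.ndarray, dtype) -> np.ndarray:
    arr = np.asarray(images, dtype=dtype)
    if arr.ndim == 3:
        arr = arr[..., None]
    return arr


def _epoch_loss(model, images, masks, weights) -> float:
    """Inference-mode compound loss over a dataset (no grads)."""
    probs = model.predict(images)
    return float(total_loss(masks[..., None].astype(np.float64),
                            probs.astype(np.float64), weights))


def _dataset_dsc(model, images, masks) -> float:
    probs = model.predict(images)
    pred = binarize(probs[..., 0])
    return segmentation_metrics(masks, pred).dsc


def train(model, train_data, val_data, cfg: TrainConfig,
          val_loss_fn=None, track_train_dsc: bool = False, stop_when=None):
    """Optimize ``model`` on ``(images, masks)`` pairs.

    ``train_data``/``val_data`` are tuples of arrays: images with shape
    (N, H, W) or (N, H, W, 1), masks with shape (N, H, W) in {0, 1}.
    ``val_data`` may be ``None``, in which case no monitoring, schedule,
    early stopping, or weight restoration happens. ``val_loss_fn``
    (mainly for contract tests) overrides how the monitored validation
    loss is computed: called as ``val_loss_fn(model, epoch)``.

    ``track_train_dsc`` adds a ``train_dsc`` entry to each history
    record (an extra inference pass per epoch); ``stop_when`` is an
    optional predicate on the epoch record that ends training once it
    returns true (e.g. a convergence target).

    Returns ``(model, history)`` where history is a list of per-epoch
    dicts (epoch, lr, train_loss, val_loss, val_dsc).
    """
    cfg.validate()
    dtype = np.dtype(model.config.dtype)
    x_train = _as_batch(train_data[0], dtype)
    y_train = np.asarray(train_data[1], dtype=dtype)
    if len(x_train) == 0:
        raise ValueError("training set is empty")
    has_val = val_data is not None or val_loss_fn is not None
    if val_data is not None:
        x_val = _as_batch(val_data[0], dtype)
        y_val = np.asarray(val_data[1], dtype=dtype)
        if len(x_val) == 0:
            raise ValueError("validation set is empty")

    rng = np.random.default_rng(cfg.rng_seed)
    optimizer = Adam(model.parameters(), lr=cfg.lr)
    weights = cfg.loss_weights
    n = len(x_train)

    best_val = np.inf
    best_state = None
    since_improve = 0
    lr_wait = 0
    history = []

    for epoch in range(1, cfg.max_epochs + 1):
        model.train()
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = Tensor(x_train[idx])
            yb = y_train[idx][..., None]
            probs = model.forward(xb)
            loss = total_loss(yb, probs, weights)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={optimizer.lr:.3g}); inspect data scaling or lower lr"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))

        record = {"epoch": epoch, "lr": optimizer.lr,
                  "train_loss": float(np.mean(epoch_losses)),
                  "val_loss": np.nan, "val_dsc": np.nan}
        if track_train_dsc:
            record["train_dsc"] = _dataset_dsc(model, x_train, y_train)

        if stop_when is not None and not has_val:
            history.append(record)
            if stop_when(record):
                break
            continue

        if has_val:
            if val_loss_fn is not None:
                val_loss = float(val_loss_fn(model, epoch))
            else:
                val_loss = _epoch_loss(model, x_val, y_val, weights)
                record["val_dsc"] = _dataset_dsc(model, x_val, y_val)
            if not np.isfinite(val_loss):
                raise TrainingDiverged(f"non-finite validation loss at epoch {epoch}")
            record["val_loss"] = val_loss
            history.append(record)

            if val_loss < best_val - cfg.min_delta:
                best_val = val_loss
                best_state = model.state_dict()
                since_improve = 0
                lr_wait = 0
            else:
                since_improve += 1
                lr_wait += 1
                if lr_wait >= cfg.lr_patience:
                    optimizer.lr *= cfg.lr_factor
                    lr_wait = 0  # wait counter restarts after a reduction
                if since_improve >= cfg.early_stop_patience:
                    break
            if stop_when is not None and stop_when(record):
                break
        else:
            history.append(record)

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def evaluate(model, test_cases, use_tta: bool = False,
             mode: str = "per-volume") -> MetricsReport:
    """Per-case metric report over ``[(case_id, images, masks), ...]``.

    ``images``: (N, H, W) array of preprocessed slices for one case;
    ``masks``: matching (N, H, W) binary array. ``mode`` is
    ``"per-volume"`` (pool all slices of the case before computing
    metrics, the default) or ``"per-slice"`` (average slice metrics
    within the case).
    """
    if mode not in ("per-volume", "per-slice"):
        raise ValueError(f"unknown evaluation mode {mode!r}")
    if not test_cases:
        raise ValueError("test set is empty")
    report = MetricsReport()
    for case_id, images, masks in test_cases:
        images = np.asarray(images)
        masks = np.asarray(masks)
        if images.size == 0:
            import warnings

            warnings.warn(f"skipping empty case {case_id}", stacklevel=2)
            continue
        if use_tta:
            probs = tta_predict(model, images[..., None])
        else:
            probs = model.predict(images)
        pred = binarize(probs[..., 0])
        if mode == "per-volume":
            record = segmentation_metrics(masks, pred, case_id=case_id)
        else:
            per_slice = [segmentation_metrics(g, p) for g, p in zip(masks, pred)]
            from .metrics import MetricsRecord

            record = MetricsRecord(
                case_id=case_id,
                dsc=float(np.mean([r.dsc for r in per_slice])),
                iou=float(np.mean([r.iou for r in per_slice])),
                precision=float(np.mean([r.precision for r in per_slice])),
                recall=float(np.mean([r.recall for r in per_slice])),
            )
        report.add(record)
    return report
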