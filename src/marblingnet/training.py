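"""Training protocol: Adam with poly learning-rate decay, batch-4
patch-based optimization, early stopping on validation marbling IoU,
and five-fold cross-validation.

Per epoch the training images are sliced into non-overlapping patches
(when ``patch_based``), augmented online, shuffled and optimized with
the configured loss; validation images are never patched and never
augmented — whole-image inference is scored by micro-aggregated
marbling IoU, and the checkpoint with the best validation IoU is kept.
All randomness (fold assignment, augmentation, data order) flows from
the config seed; weight initialization is seeded by the model config.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import data_io, evaluation
from .losses import LossConfig, loss_on_logits
from .network import MarblingNet, ModelConfig, predict_image
from .nn import Adam
from .patching import AugmentationConfig, PatchSample, augment, slice_grid

__all__ = ["TrainConfig", "FoldResult", "poly_lr", "train_fold", "cross_validate"]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the full protocol)."""
    batch_size: int = 4
    max_epochs: int = 400
    base_lr: float = 1e-4
    poly_power: float = 1.0
    early_stop_patience: int = 30
    min_delta: float = 0.0
    patch_size: int = 200
    patch_based: bool = True
    augmentation: AugmentationConfig | None = field(default_factory=AugmentationConfig)
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")


@dataclass
class FoldResult:
    """Outcome of training one cross-validation fold."""
    fold: int
    best_epoch: int
    best_val_iou: float
    train_loss: list[float]
    val_iou: list[float]
    lr: list[float]
    confusion: evaluation.ConfusionTotals
    metrics: dict[str, float]


def poly_lr(base_lr: float, epoch: int, num_epoch: int, power: float = 1.0) -> float:
    """Poly decay: lr = base_lr * (1 - epoch/num_epoch)^power."""
    if power <= 0:
        raise ValueError("power must be positive")
    if not 0 <= epoch <= num_epoch:
        raise ValueError(f"epoch {epoch} outside [0, {num_epoch}]")
    return base_lr * (1.0 - epoch / num_epoch) ** power


def _epoch_samples(data, cfg: TrainConfig, rng: np.random.Generator
                   ) -> list[PatchSample]:
    """One epoch's worth of (possibly augmented) training samples."""
    samples: list[PatchSample] = []
    for i, (image, mask) in enumerate(data):
        if cfg.patch_based:
            samples.extend(slice_grid(image, mask, cfg.patch_size, source_id=str(i)))
        else:
            samples.append(PatchSample(image=np.asarray(image),
                                       mask=np.asarray(mask), source_id=str(i)))
    if cfg.augmentation is not None:
        samples = [augment(s, cfg.augmentation, rng) for s in samples]
    rng.shuffle(samples)
    return samples


def _upsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbour mask up-sampling to match the loss grid."""
    if factor == 1:
        return mask
    return np.repeat(np.repeat(mask, factor, axis=0), factor, axis=1)


def validation_iou(model: MarblingNet, val_data) -> tuple[float, evaluation.ConfusionTotals]:
    """Micro-aggregated marbling IoU of whole-image predictions."""
    preds = [predict_image(model, img) for img, _ in val_data]
    refs = [mask for _, mask in val_data]
    totals = evaluation.confusion_totals(preds, refs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return evaluation.iou(totals), totals


def train_fold(model: MarblingNet, train_data, val_data,
               cfg: TrainConfig | None = None,
               loss_cfg: LossConfig | None = None,
               fold: int = 0, log=None) -> FoldResult:
    """Optimize ``model`` on (image, mask) pairs with the full protocol.

    ``train_data``/``val_data`` are sequences of (H x W x 3 uint8 image,
    H x W {0,1} mask) pairs; they must be disjoint sets.  Returns the
    training history with the model restored to its best-validation-IoU
    weights.  Raises on an empty training set or a non-finite loss.
    """
    cfg = cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    if len(train_data) == 0:
        raise ValueError("empty training set")
    if cfg.patch_based:
        for img, _ in train_data:
            if img.shape[0] % cfg.patch_size or img.shape[1] % cfg.patch_size:
                raise ValueError(f"image size {img.shape[:2]} not divisible by "
                                 f"patch size {cfg.patch_size}")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.base_lr)
    factor = model.cfg.upsample_factor

    history = FoldResult(fold=fold, best_epoch=0, best_val_iou=-np.inf,
                         train_loss=[], val_iou=[], lr=[],
                         confusion=evaluation.ConfusionTotals(), metrics={})
    best_state = None
    since_best = 0
    for epoch in range(cfg.max_epochs):
        lr = poly_lr(cfg.base_lr, epoch, cfg.max_epochs, cfg.poly_power)
        opt.lr = lr
        samples = _epoch_samples(train_data, cfg, rng)
        model.train()
        losses = []
        for start in range(0, len(samples), cfg.batch_size):
            chunk = samples[start:start + cfg.batch_size]
            x = np.stack([s.image for s in chunk]).astype(np.float32) / 255.0
            x = x.transpose(0, 3, 1, 2)
            y = np.stack([_upsample_mask(s.mask, factor) for s in chunk])
            logits = model.forward(x)
            loss = loss_on_logits(logits, y, loss_cfg)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite loss {loss.data!r} at epoch {epoch}, "
                                   f"batch {start // cfg.batch_size}: aborting")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        mean_loss = float(np.mean(losses))
        history.train_loss.append(mean_loss)
        history.lr.append(lr)

        if len(val_data):
            val, _ = validation_iou(model, val_data)
        else:
            val = -np.inf
        history.val_iou.append(val)
        if log is not None:
            log(epoch=epoch, lr=lr, train_loss=mean_loss, val_iou=val)
        if val > history.best_val_iou + cfg.min_delta:
            history.best_val_iou = val
            history.best_epoch = epoch + 1
            best_state = copy.deepcopy(model.state_dict())
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    if len(val_data):
        _, totals = validation_iou(model, val_data)
        history.confusion = totals
        history.metrics = evaluation.all_metrics(totals)
    return history


def _load_pairs(records) -> list[tuple[np.ndarray, np.ndarray]]:
    return [(data_io.load_image(r.image), data_io.load_mask(r.mask))
            for r in records]


def cross_validate(index: data_io.DatasetIndex, k: int = 5,
                   cfg: TrainConfig | None = None,
                   loss_cfg: LossConfig | None = None,
                   model_cfg: ModelConfig | None = None,
                   log=None) -> dict:
    """k-fold cross-validation: one freshly initialized model per fold.

    Fold assignment is (re)derived from the training seed; each run
    trains on the k-1 remaining folds and validates on the held-out
    fold.  Returns per-fold results plus micro-aggregated mean metrics.
    """
    cfg = cfg or TrainConfig()
    if len(index) < k:
        raise ValueError(f"index has {len(index)} records; need at least {k}")
    index.assign_folds(k, cfg.seed)
    results: list[FoldResult] = []
    for fold in range(k):
        train_recs, val_recs = index.split(fold)
        train_data = _load_pairs(train_recs)
        val_data = _load_pairs(val_recs)
        if not any(m.any() for _, m in val_data):
            warnings.warn(f"fold {fold}: validation set has no marbling pixels")
        mc = copy.deepcopy(model_cfg) if model_cfg else ModelConfig()
        mc.seed = cfg.seed + fold
        model = MarblingNet(mc)
        results.append(train_fold(model, train_data, val_data, cfg, loss_cfg,
                                  fold=fold, log=log))
    mean = {key: float(np.mean([r.metrics[key] for r in results]))
            for key in ("iou", "precision", "recall", "f1")}
    return {"folds": results, "mean": mean}
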