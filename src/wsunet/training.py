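"""Image-level training protocol for the weakly supervised models.

The optimiser sees only (pixels, image-label) pairs — voxel masks are
structurally withheld from the loss; they are used exclusively to compute
the per-epoch voxel-level validation trace (precision, recall, dice, AUPR)
that characterises how voxel performance drifts while image-level loss is
stable.  Training minimises image-level binary cross-entropy with Adam
(learning rate 0.001), random flip/rotation augmentation, early stopping
once the validation loss has not improved for a patience of 5 epochs, and
restoration of the best-validation weights.  Cross-validation uses
patient-disjoint folds: all patches of one subject share a fold.

A statsmodels-flavoured front door is provided by
:class:`WeaklySupervisedImageModel`, whose ``fit`` returns a
:class:`TrainingResults` carrying the trained handle, the epoch trace and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import LeakageError, UndefinedMetricError
from .metrics import aupr, precision_recall_dice, voxel_confusion
from .models import ModelHandle
from .nn import ops
from .nn.optim import Adam
from .nn.tensor import backward
from .patches import Patch, PatchDataset

__all__ = [
    "TrainingConfig",
    "FoldAssignment",
    "EpochTrace",
    "make_folds",
    "augment",
    "train_model",
    "crossvalidate",
    "WeaklySupervisedImageModel",
    "TrainingResults",
]


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.001
    patience_epochs: int = 5
    max_epochs: int = 25
    batch_size: int = 32
    n_folds: int = 5
    seed: int = 0
    augment: bool = True
    min_delta: float = 1e-4  # improvement below this counts as a plateau
    trace_voxel_metrics: bool = True

    def __post_init__(self):
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class FoldAssignment:
    fold_of_subject: Dict[str, int]

    def subjects_in(self, fold: int) -> List[str]:
        return [s for s, f in self.fold_of_subject.items() if f == fold]

    @property
    def n_folds(self) -> int:
        return max(self.fold_of_subject.values()) + 1


@dataclass
class EpochTrace:
    """Per-epoch validation records: image loss plus voxel metrics per fold."""

    records: List[Dict[str, float]] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def __len__(self) -> int:
        return len(self.records)


def make_folds(subject_ids: Sequence[str], n_folds: int, seed: int) -> FoldAssignment:
    """Shuffle subjects, deal them round-robin; fold sizes differ by <= 1."""
    subject_ids = list(subject_ids)
    if n_folds > len(subject_ids):
        raise ValueError("more folds than subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subject_ids))
    return FoldAssignment({subject_ids[j]: i % n_folds for i, j in enumerate(order)})


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _draw_transform(rng: np.random.Generator) -> Tuple[bool, bool, int]:
    return bool(rng.random() < 0.5), bool(rng.random() < 0.5), int(rng.integers(4))


def _apply_transform(grid: np.ndarray, hflip: bool, vflip: bool, k: int) -> np.ndarray:
    if hflip:
        grid = grid[:, ::-1]
    if vflip:
        grid = grid[::-1, :]
    if k:
        grid = np.rot90(grid, k)
    return np.ascontiguousarray(grid)


def augment(patch: Patch, rng: np.random.Generator) -> Patch:
    """Random horizontal/vertical flips and a rotation from {0, 90, 180, 270} deg.

    The mask undergoes the identical transform; the image-level label is
    unchanged (the transform permutes pixels).
    """
    h, w = patch.pixels.shape
    hflip, vflip, k = _draw_transform(rng)
    if h != w and k % 2:
        raise ValueError("90/270-degree rotations require square patches")
    return Patch(
        _apply_transform(patch.pixels, hflip, vflip, k), patch.label,
        _apply_transform(patch.mask, hflip, vflip, k), patch.subject_id,
        patch.centre, patch.origin, patch.source_voxel, patch.proposed_centre,
    )


def _augment_batch(xb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(xb)
    for i in range(len(xb)):
        hflip, vflip, k = _draw_transform(rng)
        out[i, ..., 0] = _apply_transform(xb[i, ..., 0], hflip, vflip, k)
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _epoch_validation(handle: ModelHandle, xv, yv, masks,
                      trace_voxels: bool) -> Dict[str, float]:
    from .nn.tensor import no_grad
    logits = []
    with no_grad():
        for i in range(0, len(xv), 64):
            logits.append(handle.forward(xv[i:i + 64])["image_logit"].data[:, 0])
    z = np.concatenate(logits).astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0) - z * yv + np.log1p(np.exp(-np.abs(z)))))
    rec: Dict[str, float] = {"val_loss": loss}
    if trace_voxels and handle.has_voxel_output and masks is not None:
        vox = handle.predict_voxels(xv)
        tp, fp, fn, _ = voxel_confusion(vox, masks)
        rec["precision"], rec["recall"], rec["dice"] = precision_recall_dice(tp, fp, fn)
        try:
            rec["aupr"] = aupr(vox, masks)
        except UndefinedMetricError:
            rec["aupr"] = float("nan")
    return rec


def train_model(handle: ModelHandle, train: PatchDataset, val: PatchDataset,
                config: TrainingConfig = TrainingConfig(),
                fold: int = 0) -> Tuple[ModelHandle, EpochTrace]:
    """Train in place with image-level supervision and early stopping.

    Masks never reach the optimiser: the loss consumes only pixels and
    image-level labels.  Validation masks feed the per-epoch voxel-metric
    trace.  The weights of the best-validation-loss epoch are restored on
    stop.  Fixed seeds and single-threaded execution give identical traces
    across runs.
    """
    overlap = set(train.subject_ids) & set(val.subject_ids)
    if overlap:
        raise LeakageError(f"subjects in both partitions: {sorted(overlap)}")

    xt, yt, _ = train.arrays()  # training masks are deliberately discarded
    xv, yv, mv = val.arrays()
    rng = np.random.default_rng(config.seed)
    opt = Adam(handle.parameters(), learning_rate=config.learning_rate)

    trace = EpochTrace()
    best_loss = np.inf
    best_weights = handle.get_weights()
    stale = 0
    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(len(xt))
        for i in range(0, len(perm), config.batch_size):
            idx = perm[i:i + config.batch_size]
            xb = xt[idx]
            if config.augment:
                xb = _augment_batch(xb, rng)
            out = handle.forward(xb, training=True, rng=rng)
            loss = ops.sigmoid_bce_with_logits(out["image_logit"], yt[idx].reshape(-1, 1))
            opt.zero_grad()
            backward(loss)
            opt.step()

        rec = _epoch_validation(handle, xv, yv, mv, config.trace_voxel_metrics)
        trace.append(epoch=epoch, fold=fold, **rec)

        if rec["val_loss"] < best_loss - config.min_delta:
            best_loss = rec["val_loss"]
            best_weights = handle.get_weights()
            stale = 0
        else:
            stale += 1
            if stale >= config.patience_epochs:
                break

    handle.set_weights(best_weights)
    return handle, trace


def crossvalidate(dataset: PatchDataset, arch_builder: Callable[[int], ModelHandle],
                  config: TrainingConfig = TrainingConfig()
                  ) -> List[Tuple[ModelHandle, EpochTrace]]:
    """One model per patient-disjoint fold, trained on the rest.

    ``arch_builder(seed)`` must return a fresh handle; fold ``k`` uses seed
    ``config.seed + k`` so that folds differ in initialisation the way
    repeated runs would.
    """
    folds = make_folds(dataset.subject_ids, config.n_folds, config.seed)
    results = []
    for k in range(config.n_folds):
        val_ids = folds.subjects_in(k)
        train_ids = [s for s in dataset.subject_ids if s not in val_ids]
        handle = arch_builder(config.seed + k)
        trained, trace = train_model(
            handle, dataset.subset(train_ids), dataset.subset(val_ids),
            config, fold=k)
        results.append((trained, trace))
    return results


# ---------------------------------------------------------------------------
# model/results front door
# ---------------------------------------------------------------------------


class WeaklySupervisedImageModel:
    """Weakly supervised classifier specification bound to a patch dataset.

    Parameters
    ----------
    dataset
        The full patch dataset; subjects are split internally.
    arch_builder
        ``seed -> ModelHandle`` (e.g. a ``partial`` of
        :func:`wsunet.models.build_wsunet`).
    config
        The training protocol.
    """

    def __init__(self, dataset: PatchDataset,
                 arch_builder: Callable[[int], ModelHandle],
                 config: TrainingConfig = TrainingConfig()):
        self.dataset = dataset
        self.arch_builder = arch_builder
        self.config = config

    def fit(self, validation_fold: int = 0) -> "TrainingResults":
        """Train on all folds but one; validate on ``validation_fold``."""
        folds = make_folds(self.dataset.subject_ids, self.config.n_folds,
                           self.config.seed)
        val_ids = folds.subjects_in(validation_fold)
        train_ids = [s for s in self.dataset.subject_ids if s not in val_ids]
        handle = self.arch_builder(self.config.seed)
        train_ds = self.dataset.subset(train_ids)
        val_ds = self.dataset.subset(val_ids)
        handle, trace = train_model(handle, train_ds, val_ds, self.config,
                                    fold=validation_fold)
        return TrainingResults(handle, trace, self.config, train_ds, val_ds)

    def fit_cv(self) -> List["TrainingResults"]:
        """Full cross-validation: one :class:`TrainingResults` per fold."""
        out = []
        for k in range(self.config.n_folds):
            out.append(self.fit(validation_fold=k))
        return out


class TrainingResults:
    """Trained handle + epoch trace + validation data, with a summary table."""

    def __init__(self, handle: ModelHandle, trace: EpochTrace,
                 config: TrainingConfig, train: PatchDataset, val: PatchDataset):
        self.handle = handle
        self.trace = trace
        self.config = config
        self.train_dataset = train
        self.val_dataset = val

    @property
    def n_epochs(self) -> int:
        return len(self.trace)

    @property
    def best_val_loss(self) -> float:
        return float(min(r["val_loss"] for r in self.trace.records))

    def predict_image(self, x: np.ndarray) -> np.ndarray:
        return self.handle.predict_image(x)

    def predict_voxels(self, x: np.ndarray) -> np.ndarray:
        return self.handle.predict_voxels(x)

    def validation_image_scores(self) -> Tuple[np.ndarray, np.ndarray]:
        xv, yv, _ = self.val_dataset.arrays()
        return self.handle.predict_image(xv), yv

    def summary(self) -> str:
        xv, yv, _ = self.val_dataset.arrays()
        scores = self.handle.predict_image(xv)
        acc = float(((scores >= 0.5) == yv).mean())
        lines = [
            "Weakly supervised image classifier",
            "==================================",
            f"architecture:          {self.handle.name}",
            f"trainable parameters:  {self.handle.trainable_parameter_count:,}",
            f"train patches:         {len(self.train_dataset)} "
            f"({len(self.train_dataset.subject_ids)} subjects)",
            f"validation patches:    {len(self.val_dataset)} "
            f"({len(self.val_dataset.subject_ids)} subjects)",
            f"epochs run:            {self.n_epochs}",
            f"best validation loss:  {self.best_val_loss:.4f}",
            f"validation accuracy:   {acc:.3f}",
        ]
        last = self.trace.records[-1]
        if "aupr" in last:
            lines.append(f"final voxel dice:      {last['dice']:.3f}")
            lines.append(f"final voxel AUPR:      {last['aupr']:.3f}")
        return "\n".join(lines)
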