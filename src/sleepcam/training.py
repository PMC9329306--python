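"""Supervised training with hold-out validation and early stopping.

Training minimizes cross-entropy over stage labels with Adam. One "iteration"
is a full pass over the training epochs. Before training, 1/6 of the epochs
are reserved for validation; training stops when the iteration count exceeds
the cap or the minimum validation loss has not improved for `patience`
consecutive iterations, and the weights from the best-validation iteration
are restored. Cross-validation partitions at the *record* level so that no
recording contributes epochs to both the train and test side of a fold, and
fold metrics are pooled by summing confusion matrices across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import EmptySplit, SingleClassData, TooFewRecords
from .evaluation import (
    ConfusionMatrix,
    MetricsReport,
    compute_metrics,
    confusion_matrix,
    pooled_metrics,
)
from .io import STAGES
from .model import ModelConfig, SleepCamModel, build_model
from .nn import cross_entropy_grad, softmax
from .preprocess import EpochSet, FilterSpec, prepare_record

_STAGE_IDX = {s: i for i, s in enumerate(STAGES)}


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings.

    The default learning rate matches full-scale training of the full-size
    network; small-cohort experiments typically raise it (see examples/).
    """

    learning_rate: float = 5e-6
    max_iterations: int = 200
    patience: int = 5
    val_fraction: float = 1.0 / 6.0
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.patience > self.max_iterations:
            raise ValueError("patience cannot exceed max_iterations")


class EarlyStopper:
    """Minimum-validation-loss early stopping with best-weights restore.

    Iterations are 1-indexed. ``update`` returns True when training must
    stop: either the iteration cap is reached or the best validation loss
    has not improved in the last ``patience`` iterations, i.e. at iteration
    min(max_iterations, best_iter + patience).
    """

    def __init__(self, patience: int, max_iterations: int):
        self.patience = patience
        self.max_iterations = max_iterations
        self.best_loss = np.inf
        self.best_iter = 0
        self.best_weights: list[np.ndarray] | None = None
        self.stopped_at: int | None = None

    def update(self, iteration: int, val_loss: float,
               weights: list[np.ndarray] | None = None) -> bool:
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_iter = iteration
            if weights is not None:
                self.best_weights = [w.copy() for w in weights]
        stop = (iteration >= self.max_iterations
                or iteration - self.best_iter >= self.patience)
        if stop:
            self.stopped_at = iteration
        return stop


@dataclass
class TrainingResult:
    """Best-validation model plus the loss history that produced it."""

    model: SleepCamModel
    history: list[tuple[float, float]]  # (train_loss, val_loss) per iteration
    stopped_at: int
    seed: int
    best_iteration: int = 0


def _onehot(labels: np.ndarray) -> np.ndarray:
    idx = np.array([_STAGE_IDX[l] for l in labels])
    out = np.zeros((len(idx), len(STAGES)), dtype=np.float32)
    out[np.arange(len(idx)), idx] = 1.0
    return out


def split_validation(epochs: EpochSet, fraction: float, seed: int
                     ) -> tuple[EpochSet, EpochSet]:
    """Disjoint seeded train/validation partition by epoch."""
    n = len(epochs)
    n_val = int(round(fraction * n))
    if n_val < 1 or n_val >= n:
        raise EmptySplit(f"fraction {fraction} leaves an empty side for n={n}")
    order = np.random.default_rng(seed).permutation(n)
    return epochs.subset(order[n_val:]), epochs.subset(order[:n_val])


def _dataset_loss(model: SleepCamModel, epochs: EpochSet, onehot: np.ndarray,
                  batch_size: int) -> float:
    total, n = 0.0, len(epochs)
    for lo in range(0, n, batch_size):
        sub = epochs.subset(range(lo, min(lo + batch_size, n)))
        _, logits = model.forward_batch(sub.eeg, sub.eog, sub.emg)
        p = softmax(logits.astype(np.float64), axis=1)
        y = onehot[lo: lo + len(sub)]
        total += float(-(y * np.log(np.maximum(p, 1e-12))).sum())
    return total / n


def train_model(config: ModelConfig, tconfig: TrainingConfig,
                epochs: EpochSet) -> TrainingResult:
    """Fit Sleep-CAM on labelled epochs with Adam + early stopping."""
    if len(epochs) == 0:
        raise SingleClassData("no training epochs")
    if len(set(epochs.labels.tolist())) < 2:
        raise SingleClassData("training data contain fewer than two stages")

    train, val = split_validation(epochs, tconfig.val_fraction, tconfig.seed)
    y_train = _onehot(train.labels)
    y_val = _onehot(val.labels)

    model = build_model(config)
    opt = model.make_optimizer(tconfig.learning_rate)
    stopper = EarlyStopper(tconfig.patience, tconfig.max_iterations)
    rng = np.random.default_rng(tconfig.seed + 1)
    history: list[tuple[float, float]] = []

    for iteration in range(1, tconfig.max_iterations + 1):
        order = rng.permutation(len(train))
        loss_sum = 0.0
        for lo in range(0, len(order), tconfig.batch_size):
            idx = order[lo: lo + tconfig.batch_size]
            sub = train.subset(idx)
            _, logits = model.forward_batch(sub.eeg, sub.eog, sub.emg)
            loss, dlogits = cross_entropy_grad(logits, y_train[idx])
            model.backward(dlogits)
            opt.step(model.grads)
            loss_sum += loss * len(idx)
        train_loss = loss_sum / len(order)
        val_loss = _dataset_loss(model, val, y_val, tconfig.batch_size)
        history.append((train_loss, val_loss))
        if stopper.update(iteration, val_loss, model.get_weights()):
            break

    if stopper.best_weights is not None:
        model.set_weights(stopper.best_weights)
    return TrainingResult(
        model=model, history=history, stopped_at=stopper.stopped_at or 0,
        seed=tconfig.seed, best_iteration=stopper.best_iter,
    )


# ----------------------------------------------------------------------
# record-wise experiments
# ----------------------------------------------------------------------

def _as_epoch_sets(records, filters: dict[str, FilterSpec] | None) -> list[EpochSet]:
    out = []
    for item in records:
        if isinstance(item, EpochSet):
            out.append(item)
        else:
            rec, hyp = item
            out.append(prepare_record(rec, hyp, filters))
    return out


@dataclass
class CrossValResult:
    report: MetricsReport
    fold_models: list[SleepCamModel]
    fold_matrices: list[ConfusionMatrix]
    fold_assignment: dict[str, int] = field(default_factory=dict)


def cross_validate(
    records: Sequence,
    k: int,
    model_config: ModelConfig,
    train_config: TrainingConfig,
    seed: int = 0,
    filters: dict[str, FilterSpec] | None = None,
) -> CrossValResult:
    """k-fold cross-validation partitioned by record.

    ``records`` holds (PsgRecord, Hypnogram) pairs (preprocessed internally)
    or ready EpochSet objects. Records are shuffled by ``seed`` and dealt
    into k near-equal folds; each fold is tested once by a model trained on
    the remaining records, and the fold confusion matrices are summed before
    computing the pooled metrics.
    """
    sets = _as_epoch_sets(records, filters)
    if len(sets) < k:
        raise TooFewRecords(f"{len(sets)} records for {k} folds")
    order = np.random.default_rng(seed).permutation(len(sets))
    assignment = {str(sets[r].record_ids[0]): int(i % k)
                  for i, r in enumerate(order)}
    fold_of = np.empty(len(sets), dtype=int)
    for i, r in enumerate(order):
        fold_of[r] = i % k

    fold_models, fold_cms = [], []
    for fold in range(k):
        test_idx = [i for i in range(len(sets)) if fold_of[i] == fold]
        train_idx = [i for i in range(len(sets)) if fold_of[i] != fold]
        train_set = EpochSet.concatenate([sets[i] for i in train_idx])
        test_set = EpochSet.concatenate([sets[i] for i in test_idx])
        overlap = set(train_set.record_ids) & set(test_set.record_ids)
        if overlap:
            raise AssertionError(f"record leakage across folds: {overlap}")
        result = train_model(model_config, train_config, train_set)
        pred = result.model.predict(test_set)
        fold_models.append(result.model)
        fold_cms.append(confusion_matrix(test_set.labels, pred))
    return CrossValResult(
        report=pooled_metrics(fold_cms), fold_models=fold_models,
        fold_matrices=fold_cms, fold_assignment=assignment,
    )


def learning_curve(
    records: Sequence,
    sizes: Sequence[int],
    model_config: ModelConfig,
    train_config: TrainingConfig,
    seed: int = 0,
    holdout_fraction: float = 0.25,
    filters: dict[str, FilterSpec] | None = None,
) -> dict[int, float]:
    """Accuracy on a fixed held-out record set vs. training-cohort size.

    Duplicate sizes are deduplicated and each size is run once on a seeded
    random record subset of that size.
    """
    sets = _as_epoch_sets(records, filters)
    sizes = sorted(set(int(s) for s in sizes))
    if any(s < 1 for s in sizes):
        raise TooFewRecords("training subset size must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sets))
    n_hold = max(1, int(round(holdout_fraction * len(sets))))
    hold_idx, pool_idx = order[:n_hold], order[n_hold:]
    if sizes and max(sizes) > len(pool_idx):
        raise TooFewRecords(
            f"largest size {max(sizes)} exceeds {len(pool_idx)} available records"
        )
    holdout = EpochSet.concatenate([sets[i] for i in hold_idx])

    out: dict[int, float] = {}
    for size in sizes:
        chosen = rng.choice(pool_idx, size=size, replace=False)
        train_set = EpochSet.concatenate([sets[i] for i in chosen])
        result = train_model(model_config, train_config, train_set)
        pred = result.model.predict(holdout)
        out[size] = compute_metrics(confusion_matrix(holdout.labels, pred)).accuracy
    return out
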