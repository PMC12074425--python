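"""Patient-specific leave-one-record-out training of the detector.

The detector consumes broadband (notch-filtered, z-scored, not band-split)
4-s windows of the M selected channels. A window's ground-truth label is
ictal when at least half of its 4-s span overlaps an annotated seizure.
Training windows are cut at 2-s stride on seizure-containing records and
4-s stride on seizure-free records to bound the dataset size; evaluation
always uses the 2-s stride.

Seizures are rare, so batches are class-aware: each batch of 64 holds
exactly 3 minority-class windows (5% of 64, drawn with replacement when
fewer remain) and 61 majority windows; with no minority samples at all,
plain shuffled batches. One epoch covers the majority class once. Training
runs at most 150 epochs with Adam (lr 1e-3, beta1 0.9, beta2 0.999), stops
after 10 epochs without validation-loss improvement, and restores the
weights of the best validation epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .data_io import EEGRecord, SeizureAnnotation
from .evaluation import window_truth
from .model import SeizureCNN, WINDOW_SAMPLES
from .preprocess import WindowSpec, make_windows

INTER_ICTAL, ICTAL_CLASS = 0, 1

#: window geometry of the detector (4-s windows, 2-s stride)
EVAL_WINDOW = WindowSpec(length_s=4.0, stride_s=2.0)
#: stride used on seizure-free records during training
FREE_STRIDE_S = 4.0


class TrainingError(Exception):
    pass


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    minority_fraction: float = 0.05
    max_epochs: int = 150
    patience: int = 10
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0

    @property
    def minority_per_batch(self) -> int:
        return int(self.minority_fraction * self.batch_size)


@dataclass(frozen=True)
class LoroFold:
    test_record: str
    val_records: tuple[str, ...]
    train_records: tuple[str, ...]


@dataclass
class WindowDataset:
    """Windowed samples of one record: X (n, 1, M, T), y (n,), start times."""

    record_id: str
    X: np.ndarray
    y: np.ndarray
    starts_s: np.ndarray


@dataclass
class FoldResult:
    fold: LoroFold
    model: SeizureCNN
    history: list[dict[str, float]]
    best_epoch: int


def window_label(start_s: float, length_s: float,
                 annotations: list[SeizureAnnotation]) -> int:
    """Ictal iff >= 50% of the window's span overlaps an annotated seizure.

    The same rule defines segment ground truth in :mod:`.evaluation`.
    """
    return ICTAL_CLASS if window_truth(start_s, length_s, annotations) else INTER_ICTAL


def build_windows(record: EEGRecord, annotations: list[SeizureAnnotation],
                  channels: list[int], stride_s: float | None = None) -> WindowDataset:
    """Cut one preprocessed record into labelled detector windows.

    ``channels`` are 1-based canonical montage numbers; the samples matrix
    must already be broadband-preprocessed. Default stride: 2 s on seizure
    records, 4 s on seizure-free ones.
    """
    if stride_s is None:
        stride_s = EVAL_WINDOW.stride_s if annotations else FREE_STRIDE_S
    rows = [c - 1 for c in channels]
    sig = record.samples[rows]
    spec = WindowSpec(length_s=EVAL_WINDOW.length_s, stride_s=stride_s)
    wins = make_windows(sig, record.fs, spec)
    if not wins:
        raise TrainingError(f"record {record.record_id} shorter than one window")
    X = np.stack([w[np.newaxis] for _, w in wins])
    starts = np.array([t for t, _ in wins])
    y = np.array([window_label(t, spec.length_s, annotations) for t in starts], dtype=int)
    return WindowDataset(record.record_id, X, y, starts)


def loro_folds(record_ids: list[str], seizure_record_ids: set[str],
               seed: int = 0) -> list[LoroFold]:
    """One fold per record (seizure-free records included as test folds).

    The validation record is one seizure-containing record from the
    remainder when possible, else an arbitrary remaining record; the rest
    train. Deterministic given the record order and seed.
    """
    if len(record_ids) < 3:
        raise TrainingError("leave-one-record-out needs at least 3 records")
    rng = np.random.default_rng(seed)
    folds = []
    for test in record_ids:
        rest = [r for r in record_ids if r != test]
        with_seizure = [r for r in rest if r in seizure_record_ids]
        pool = with_seizure if with_seizure else rest
        val = pool[int(rng.integers(len(pool)))]
        folds.append(LoroFold(
            test_record=test,
            val_records=(val,),
            train_records=tuple(r for r in rest if r != val),
        ))
    return folds


def balanced_batches(y: np.ndarray, cfg: TrainConfig, rng: np.random.Generator):
    """Yield index arrays forming one epoch of class-aware batches.

    Each batch: ``minority_per_batch`` minority samples (with replacement
    if fewer remain unseen) + the rest majority. The majority class is
    covered exactly once per epoch; without minority samples, plain
    shuffled batches of ``batch_size``.
    """
    y = np.asarray(y)
    minority = np.flatnonzero(y == ICTAL_CLASS)
    majority = np.flatnonzero(y == INTER_ICTAL)
    if minority.size == 0 or majority.size == 0:
        idx = rng.permutation(y.size)
        for i in range(0, y.size, cfg.batch_size):
            batch = idx[i:i + cfg.batch_size]
            if batch.size:
                yield batch
        return
    k = cfg.minority_per_batch
    n_major = cfg.batch_size - k
    perm_major = rng.permutation(majority)
    perm_minor = rng.permutation(minority)
    cursor_minor = 0
    if perm_major.size < n_major:
        # degenerate near-balanced data: a single undersized batch
        yield rng.permutation(np.concatenate([perm_major, perm_minor[:k]]))
        return
    for i in range(0, perm_major.size, n_major):
        major_part = perm_major[i:i + n_major]
        if major_part.size < n_major:
            break
        if cursor_minor + k <= perm_minor.size:
            minor_part = perm_minor[cursor_minor:cursor_minor + k]
            cursor_minor += k
        else:
            minor_part = rng.choice(minority, size=k, replace=True)
        batch = np.concatenate([major_part, minor_part])
        yield rng.permutation(batch)


def train_model(X_train: np.ndarray, y_train: np.ndarray,
                X_val: np.ndarray, y_val: np.ndarray,
                cfg: TrainConfig = TrainConfig(), M: int | None = None
                ) -> tuple[SeizureCNN, list[dict[str, float]], int]:
    """Train one detector with early stopping; returns the best-epoch model.

    The history records mean train loss and validation loss per epoch;
    ``best_epoch`` is the (0-based) epoch whose weights are restored.
    """
    if X_train.shape[0] == 0:
        raise TrainingError("empty training set")
    if M is None:
        M = X_train.shape[2]
    model = SeizureCNN(M, seed=cfg.seed)
    optimizer = nn.Adam(model.net.params(), lr=cfg.learning_rate,
                        beta1=cfg.beta1, beta2=cfg.beta2)
    rng = np.random.default_rng(cfg.seed + 1)
    history: list[dict[str, float]] = []
    best_val = np.inf
    best_state = model.state()
    best_epoch = 0
    for epoch in range(cfg.max_epochs):
        losses = [model.train_step(X_train[b], y_train[b], optimizer)
                  for b in balanced_batches(y_train, cfg, rng)]
        val_loss = model.loss_on(X_val, y_val)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.state()
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            break
    model.load_state(best_state)
    return model, history, best_epoch


def train_patient(datasets: dict[str, WindowDataset], folds: list[LoroFold],
                  cfg: TrainConfig = TrainConfig()) -> list[FoldResult]:
    """Run every LORO fold; test-record windows never touch training."""
    results = []
    for fold in folds:
        train_ids = set(fold.train_records)
        val_ids = set(fold.val_records)
        if fold.test_record in train_ids | val_ids:
            raise TrainingError("test record leaked into training/validation")
        X_train = np.concatenate([datasets[r].X for r in fold.train_records])
        y_train = np.concatenate([datasets[r].y for r in fold.train_records])
        X_val = np.concatenate([datasets[r].X for r in fold.val_records])
        y_val = np.concatenate([datasets[r].y for r in fold.val_records])
        model, history, best_epoch = train_model(X_train, y_train, X_val, y_val, cfg)
        results.append(FoldResult(fold, model, history, best_epoch))
    return results
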