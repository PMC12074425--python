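"""LORO fold construction, class-aware batches, and training mechanics."""

import numpy as np
import pytest

from seizelect.data_io import SeizureAnnotation
from seizelect.model import SeizureCNN
from seizelect.training import (LoroFold, TrainConfig, TrainingError,
                                balanced_batches, build_windows, loro_folds,
                                train_model, train_patient, window_label,
                                WindowDataset)

from conftest import make_record


# -- labels and window datasets ---------------------------------------------

@pytest.mark.parametrize("start,expected", [
    (90.0, 0),    # no overlap
    (97.0, 0),    # 1 s overlap < half the window
    (98.0, 1),    # exactly half: counts as ictal
    (110.0, 1),   # fully inside
    (137.0, 1),   # 3 s overlap
    (139.0, 0),   # 1 s overlap at the tail
])
def test_window_label_half_overlap_rule(start, expected):
    anns = [SeizureAnnotation("r", 100.0, 140.0)]
    assert window_label(start, 4.0, anns) == expected


def test_build_windows_strides(rng):
    rec = make_record(rng.standard_normal((21, 256 * 60)))
    anns = [SeizureAnnotation("test_01", 20.0, 35.0)]
    ds_seiz = build_windows(rec, anns, [19, 9])
    assert ds_seiz.X.shape == (29, 1, 2, 1024)   # 2-s stride on seizure records
    assert ds_seiz.y.sum() == len([t for t in ds_seiz.starts_s
                                   if window_label(t, 4.0, anns)])
    ds_free = build_windows(rec, [], [19, 9])
    assert ds_free.X.shape[0] == 15              # 4-s stride on seizure-free ones
    assert ds_free.y.sum() == 0


# -- folds ------------------------------------------------------------------

def test_loro_folds_partition_and_cover():
    ids = [f"r{i}" for i in range(5)]
    folds = loro_folds(ids, seizure_record_ids={"r0", "r2"}, seed=0)
    assert [f.test_record for f in folds] == ids
    for f in folds:
        parts = {f.test_record, *f.val_records, *f.train_records}
        assert parts == set(ids)
        assert len(f.val_records) == 1
        assert f.test_record not in f.train_records + f.val_records
        # validation prefers a seizure-containing record
        assert f.val_records[0] in {"r0", "r2"} - {f.test_record}


def test_loro_includes_seizure_free_test_folds():
    folds = loro_folds(["a", "b", "c"], seizure_record_ids={"a"}, seed=1)
    assert "c" in [f.test_record for f in folds]


def test_loro_requires_three_records():
    with pytest.raises(TrainingError):
        loro_folds(["a", "b"], set(), seed=0)


# -- balanced batches -------------------------------------------------------

def test_balanced_batch_composition(rng):
    y = np.array([0] * 1000 + [1] * 50)
    cfg = TrainConfig()
    batches = list(balanced_batches(y, cfg, rng))
    assert len(batches) == 1000 // 61
    for b in batches:
        assert b.size == 64
        assert (y[b] == 1).sum() == 3    # exactly 5% of 64 minority samples
    # majority covered at most once across the epoch
    major_used = np.concatenate([b[y[b] == 0] for b in batches])
    assert len(set(major_used)) == len(major_used)


def test_balanced_batches_resample_scarce_minority(rng):
    y = np.array([0] * 200 + [1])      # single minority window
    for b in balanced_batches(y, TrainConfig(), rng):
        assert (y[b] == 1).sum() == 3  # drawn with replacement


def test_batches_without_minority_are_plain(rng):
    y = np.zeros(130, dtype=int)
    batches = list(balanced_batches(y, TrainConfig(), rng))
    assert sorted(np.concatenate(batches).tolist()) == list(range(130))


def test_batches_are_deterministic_given_seed():
    y = np.array([0] * 300 + [1] * 10)
    a = [b.tolist() for b in balanced_batches(y, TrainConfig(), np.random.default_rng(9))]
    b = [b.tolist() for b in balanced_batches(y, TrainConfig(), np.random.default_rng(9))]
    assert a == b


# -- training loop ----------------------------------------------------------

def _toy_data(rng, n=440, minority_every=10, separation=3.0):
    """Linearly separable, imbalanced toy windows: the rare class has a
    mean offset."""
    X = rng.standard_normal((n, 1, 2, 1024)).astype(np.float32)
    y = (np.arange(n) % minority_every == 0).astype(int)
    X[y == 1] += separation
    return X, y


def test_training_learns_separable_data(rng):
    """Validation loss decreases and the restored model separates the
    classes; the restored epoch is the validation-loss minimum."""
    X, y = _toy_data(rng)
    cfg = TrainConfig(seed=0, max_epochs=25, patience=25)
    model, history, best_epoch = train_model(X, y, X, y, cfg)
    assert history[-1]["val_loss"] < history[0]["val_loss"]
    assert history[best_epoch]["val_loss"] == min(h["val_loss"] for h in history)
    assert (model.predict(X) == y).mean() >= 0.95


def test_patience_semantics():
    """Training halts exactly patience epochs past the best one."""
    X = np.zeros((70, 1, 2, 1024), dtype=np.float32)
    y = np.zeros(70, dtype=int)
    cfg = TrainConfig(seed=0, max_epochs=50, patience=4)
    _, history, best_epoch = train_model(X, y, X, y, cfg)
    assert len(history) == best_epoch + cfg.patience + 1


def test_training_is_deterministic(rng):
    X, y = _toy_data(rng, n=130)
    cfg = TrainConfig(seed=3, max_epochs=3, patience=10)
    _, h1, _ = train_model(X, y, X, y, cfg)
    _, h2, _ = train_model(X, y, X, y, cfg)
    assert h1 == h2


def test_empty_training_set_errors():
    X = np.zeros((0, 1, 2, 1024), dtype=np.float32)
    with pytest.raises(TrainingError):
        train_model(X, np.zeros(0, dtype=int), X, np.zeros(0, dtype=int))


def test_train_patient_rejects_leaky_folds(rng):
    X, y = _toy_data(rng, n=10, minority_every=2)
    ds = {r: WindowDataset(r, X, y, np.arange(10.0)) for r in ("a", "b", "c")}
    bad = [LoroFold(test_record="a", val_records=("a",), train_records=("b", "c"))]
    with pytest.raises(TrainingError, match="leaked"):
        train_patient(ds, bad)
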