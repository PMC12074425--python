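"""End-to-end patient workflows: select a pair, train LORO folds, evaluate.

These are the entry points the CLI and the acceptance checks drive; each
stage is also usable on its own through the underlying modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import EEGRecord, SeizureAnnotation
from .evaluation import RecordEvaluation, aggregate, evaluate_record
from .montage import DEFAULT_SCHEME, TEMPORAL4_LABELS
from .preprocess import preprocess_record
from .selection import (ChannelPair, RecordPhaseStats, SelectionResult,
                        record_phase_stats, select_from_stats, select_with_loro,
                        DEFAULT_GUARD_S, DEFAULT_THRESHOLD)
from .training import (TrainConfig, WindowDataset, build_windows, loro_folds,
                       train_patient)


@dataclass
class PatientData:
    records: list[EEGRecord]
    annotations: dict[str, list[SeizureAnnotation]]

    @property
    def patient_id(self) -> str:
        return self.records[0].patient_id

    def seizure_record_ids(self) -> set[str]:
        return {rid for rid, anns in self.annotations.items() if anns}


def preprocess_patient(data: PatientData, powerline_hz: float = 60.0) -> PatientData:
    """Broadband conditioning (notch + z-score) of every record."""
    return PatientData(
        records=[preprocess_record(r, powerline_hz=powerline_hz) for r in data.records],
        annotations=data.annotations,
    )


def select_channels(data: PatientData, guard_s: float = DEFAULT_GUARD_S,
                    threshold: float = DEFAULT_THRESHOLD,
                    preprocessed: bool = False,
                    powerline_hz: float = 60.0
                    ) -> tuple[ChannelPair, list[ChannelPair]]:
    """Leave-one-record-out channel-pair selection with majority voting."""
    pair, fold_pairs, _ = select_channels_detailed(
        data, guard_s=guard_s, threshold=threshold,
        preprocessed=preprocessed, powerline_hz=powerline_hz)
    return pair, fold_pairs


def select_channels_detailed(data: PatientData, guard_s: float = DEFAULT_GUARD_S,
                             threshold: float = DEFAULT_THRESHOLD,
                             preprocessed: bool = False,
                             powerline_hz: float = 60.0
                             ) -> tuple[ChannelPair, list[ChannelPair], SelectionResult]:
    """As :func:`select_channels`, additionally returning the all-records
    phase maps, SCT map and candidate sets (for reporting/plotting)."""
    stats: list[RecordPhaseStats] = [
        record_phase_stats(rec, data.annotations.get(rec.record_id, []),
                           guard_s=guard_s, preprocessed=preprocessed,
                           powerline_hz=powerline_hz)
        for rec in data.records
    ]
    pair, fold_pairs = select_with_loro(stats, threshold=threshold)
    full = select_from_stats(stats, threshold=threshold)
    return pair, fold_pairs, full


def temporal4_channels() -> list[int]:
    """Canonical numbers of the fixed four-temporal baseline montage."""
    return [DEFAULT_SCHEME.number(lb) for lb in TEMPORAL4_LABELS]


def detect_patient(data: PatientData, channels: list[int],
                   cfg: TrainConfig = TrainConfig(),
                   preprocessed: bool = False,
                   powerline_hz: float = 60.0
                   ) -> tuple[list[RecordEvaluation], dict[str, float], list]:
    """Train one LORO fold per record and score each held-out record.

    Returns per-record evaluations, the patient-level aggregate, and the
    trained fold results.
    """
    if not preprocessed:
        data = preprocess_patient(data, powerline_hz=powerline_hz)
    datasets: dict[str, WindowDataset] = {}
    eval_sets: dict[str, WindowDataset] = {}
    for rec in data.records:
        anns = data.annotations.get(rec.record_id, [])
        datasets[rec.record_id] = build_windows(rec, anns, channels)
        # evaluation always at the 2-s stride, whatever the training stride
        eval_sets[rec.record_id] = (
            datasets[rec.record_id] if anns else build_windows(rec, anns, channels, stride_s=2.0)
        )
    folds = loro_folds([r.record_id for r in data.records],
                       data.seizure_record_ids(), seed=cfg.seed)
    results = train_patient(datasets, folds, cfg)
    evaluations = []
    durations = {r.record_id: r.duration_s for r in data.records}
    for res in results:
        rid = res.fold.test_record
        ds = eval_sets[rid]
        preds = res.model.predict(ds.X)
        evaluations.append(evaluate_record(
            rid, list(zip(ds.starts_s, preds)),
            data.annotations.get(rid, []), durations[rid]))
    return evaluations, aggregate(evaluations), results


def oracle_evaluation(data: PatientData, channels: list[int] | None = None
                      ) -> tuple[list[RecordEvaluation], dict[str, float]]:
    """Score perfect window predictions (truth labels fed back as predictions).

    An identity harness: with flawless windows the segment metrics must be
    perfect and no false-positive events can appear.
    """
    from .training import window_label

    evaluations = []
    for rec in data.records:
        anns = data.annotations.get(rec.record_id, [])
        starts = np.arange(0.0, rec.duration_s - 4.0 + 1e-9, 2.0)
        preds = [(t, window_label(t, 4.0, anns)) for t in starts]
        evaluations.append(evaluate_record(rec.record_id, preds, anns, rec.duration_s))
    return evaluations, aggregate(evaluations)
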