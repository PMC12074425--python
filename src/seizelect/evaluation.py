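"""Segment- and event-level scoring of window predictions.

A *segment* is a buffer of three consecutive 4-s windows at 2-s stride
(an 8-s span advancing by 2 s). A segment is predicted ictal only when
all three windows are predicted ictal — a rule deliberately stricter than
majority voting over the buffer, which suppresses isolated false-positive
windows. Segment ground truth applies the same buffer to the ground-truth
window labels (a window is truth-ictal when at least half its span
overlaps an annotated seizure): the truth and prediction rules coincide,
so flawless window predictions score perfectly, including at seizure
boundaries.

Segment-level confusion counts give sensitivity SN = TP/(TP+FN),
specificity SP = TN/(TN+FP), accuracy, and balanced accuracy
bAcc = (SN+SP)/2; an undefined ratio (no positives, or no negatives) is
reported as NaN, never silently as 0.

At the event level, maximal runs of ictal-predicted segments merge into
predicted events. An annotated seizure counts as detected when at least
one predicted event overlaps it; the detection delay is the start of the
earliest overlapping segment minus the annotated onset, clipped below at
zero. A predicted event overlapping no annotation is one false-positive
event, reported as events per hour of recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import SeizureAnnotation

SEGMENT_WINDOWS = 3          # windows per segment buffer
SEGMENT_SPAN_S = 8.0         # 3 windows of 4 s at 2-s stride


@dataclass(frozen=True)
class SegmentPrediction:
    start_s: float
    end_s: float
    predicted: int  # 1 ictal, 0 inter-ictal
    truth: int


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricSet:
    SN: float
    SP: float
    Acc: float
    bAcc: float


@dataclass
class EventReport:
    detected: int
    total: int
    delays_s: list[float]
    fp_events: int
    record_duration_h: float

    @property
    def fp_per_hour(self) -> float:
        return self.fp_events / self.record_duration_h


def window_truth(start_s: float, length_s: float,
                 annotations: list[SeizureAnnotation]) -> int:
    """Ground-truth window label: ictal iff >= 50% of the span overlaps an
    annotated seizure (intervals are half-open)."""
    end_s = start_s + length_s
    overlap = sum(max(0.0, min(end_s, a.offset_s) - max(start_s, a.onset_s))
                  for a in annotations)
    return int(overlap >= length_s / 2.0)


def windows_to_segments(window_preds: list[tuple[float, int]],
                        annotations: list[SeizureAnnotation],
                        window_length_s: float = 4.0) -> list[SegmentPrediction]:
    """Fold ordered (start_s, predicted label) windows into scored segments.

    Windows must be at the 2-s evaluation stride; fewer than three windows
    yield no segments. Prediction and truth both use the all-three rule
    (see module docstring).
    """
    preds = sorted(window_preds)
    segments = []
    for k in range(len(preds) - SEGMENT_WINDOWS + 1):
        triple = preds[k:k + SEGMENT_WINDOWS]
        start = triple[0][0]
        end = start + SEGMENT_SPAN_S
        predicted = int(all(lbl == 1 for _, lbl in triple))
        truth = int(all(window_truth(t, window_length_s, annotations)
                        for t, _ in triple))
        segments.append(SegmentPrediction(start, end, predicted, truth))
    return segments


def confusion(segments: list[SegmentPrediction]) -> ConfusionCounts:
    c = ConfusionCounts()
    for s in segments:
        if s.truth and s.predicted:
            c.TP += 1
        elif s.truth and not s.predicted:
            c.FN += 1
        elif not s.truth and s.predicted:
            c.FP += 1
        else:
            c.TN += 1
    return c


def metrics(c: ConfusionCounts) -> MetricSet:
    """SN, SP, Acc, bAcc; undefined ratios become NaN."""
    sn = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else float("nan")
    sp = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else float("nan")
    acc = (c.TP + c.TN) / c.total if c.total else float("nan")
    bacc = (sn + sp) / 2.0
    return MetricSet(SN=sn, SP=sp, Acc=acc, bAcc=bacc)


def events_from_segments(segments: list[SegmentPrediction]
                         ) -> list[tuple[float, float]]:
    """Maximal runs of ictal-predicted segments as (start_s, end_s) events."""
    events = []
    run_start = None
    run_end = None
    for s in segments:
        if s.predicted:
            if run_start is None:
                run_start = s.start_s
            run_end = s.end_s
        elif run_start is not None:
            events.append((run_start, run_end))
            run_start = None
    if run_start is not None:
        events.append((run_start, run_end))
    return events


def event_metrics(events: list[tuple[float, float]],
                  annotations: list[SeizureAnnotation],
                  duration_h: float) -> EventReport:
    """Detected-seizure count, per-seizure delays and FP events per hour."""
    delays = []
    detected = 0
    matched = np.zeros(len(events), dtype=bool)
    for a in annotations:
        hit_starts = []
        for i, (e0, e1) in enumerate(events):
            if min(e1, a.offset_s) > max(e0, a.onset_s):
                matched[i] = True
                hit_starts.append(e0)
        if hit_starts:
            detected += 1
            delays.append(max(0.0, min(hit_starts) - a.onset_s))
    fp_events = int((~matched).sum())
    return EventReport(detected=detected, total=len(annotations),
                       delays_s=delays, fp_events=fp_events,
                       record_duration_h=duration_h)


@dataclass
class RecordEvaluation:
    record_id: str
    counts: ConfusionCounts
    metrics: MetricSet
    events: EventReport


def evaluate_record(record_id: str, window_preds: list[tuple[float, int]],
                    annotations: list[SeizureAnnotation],
                    duration_s: float) -> RecordEvaluation:
    """Full segment + event scoring of one test record's window predictions.

    Seizure-free records naturally contribute specificity and FP rate
    only; their SN comes out NaN.
    """
    segments = windows_to_segments(window_preds, annotations)
    c = confusion(segments)
    events = events_from_segments(segments)
    return RecordEvaluation(
        record_id=record_id,
        counts=c,
        metrics=metrics(c),
        events=event_metrics(events, annotations, duration_s / 3600.0),
    )


def aggregate(evaluations: list[RecordEvaluation]) -> dict[str, float]:
    """Patient-level mean and standard deviation across records.

    NaN metrics (e.g. SN of seizure-free records) are excluded from the
    means; events and delays pool across records.
    """
    def _ms(values):
        v = np.array([x for x in values if not np.isnan(x)])
        if v.size == 0:
            return float("nan"), float("nan")
        return float(v.mean()), float(v.std())

    sn_m, sn_s = _ms([e.metrics.SN for e in evaluations])
    sp_m, sp_s = _ms([e.metrics.SP for e in evaluations])
    bacc_m, bacc_s = _ms([e.metrics.bAcc for e in evaluations])
    delays = [d for e in evaluations for d in e.events.delays_s]
    total_h = sum(e.events.record_duration_h for e in evaluations)
    fp_total = sum(e.events.fp_events for e in evaluations)
    return {
        "SN_mean": sn_m, "SN_sd": sn_s,
        "SP_mean": sp_m, "SP_sd": sp_s,
        "bAcc_mean": bacc_m, "bAcc_sd": bacc_s,
        "delay_mean_s": float(np.mean(delays)) if delays else float("nan"),
        "delay_sd_s": float(np.std(delays)) if delays else float("nan"),
        "fp_per_hour": fp_total / total_h if total_h else float("nan"),
        "detected": sum(e.events.detected for e in evaluations),
        "total_seizures": sum(e.events.total for e in evaluations),
    }
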