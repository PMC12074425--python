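"""Patient-specific channel-pair selection from CWC phase maps.

The pipeline condenses the per-second, per-band channel weights into one
number per channel and phase (ictal vs no-seizure), then picks one
representative channel per phase:

1. average the CWC series over the 1-s windows belonging to each phase,
   per band (``phase_mean_cwc``);
2. min-max normalize each band's 21-vector across channels and average
   the five bands with equal weight (``merge_bands``);
3. average the per-record merged maps across the patient's seizure
   records and rescale to [0, 1] (``average_records``);
4. digitize each phase map at a threshold (default 0.9, strict ``>``) and
   XOR the two bit vectors, keeping channels dominant in exactly one
   phase (``digitize`` / ``xor_candidates``);
5. when several candidates survive, keep the least-correlated pair by the
   mean absolute Pearson correlation over 1-s windows and the five bands
   (``mean_abs_pcc`` / ``select_pair``);
6. run the whole procedure once per leave-one-record-out fold and
   majority-vote the per-fold pairs (``select_with_loro``) so the
   detector-facing pair never depends on a single held-out record.

Channels are identified throughout by their canonical 1-based montage
number (1..21); ``channel_a`` represents the no-seizure phase, ``channel_b``
the ictal phase.

The no-seizure phase of a seizure record excludes a configurable guard
before onset and after offset (default 600 s for hour-long clinical
records) because the pre-ictal regime is visibly distinct but has no
detector; the guard is the reproducible surrogate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .cwc import CWCSeries, cwc_series
from .data_io import EEGRecord, SeizureAnnotation
from .preprocess import BAND_NAMES, BandDecomposition, band_decompose, preprocess_record

ICTAL = "ictal"
NO_SEIZURE = "no_seizure"

#: Default guards (s) excluded around each seizure from the no-seizure phase.
DEFAULT_GUARD_S = 600.0
#: Default digitization threshold on [0, 1]-scaled phase maps.
DEFAULT_THRESHOLD = 0.9


class SelectionError(Exception):
    pass


class EmptyPhaseError(SelectionError):
    """No 1-s window falls inside the requested phase."""


@dataclass(frozen=True)
class PhaseInterval:
    phase: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"empty interval [{self.start_s}, {self.end_s})")


@dataclass
class PhaseMap:
    phase: str
    values: np.ndarray  # (21,), in [0, 1] after final rescale
    n_records: int


@dataclass
class SCTMap:
    """Digitized phase maps and their XOR (the selected-channels map)."""

    bits_ictal: np.ndarray
    bits_no_seizure: np.ndarray

    @property
    def xor_bits(self) -> np.ndarray:
        return np.logical_xor(self.bits_ictal, self.bits_no_seizure)


@dataclass(order=True)
class ChannelPair:
    """Selected (no-seizure, ictal) channel pair, 1-based canonical numbers."""

    channel_a: int
    channel_b: int
    rho_bar: float = field(compare=False, default=float("nan"))

    def __post_init__(self) -> None:
        if self.channel_a == self.channel_b:
            raise ValueError("pair channels must differ")


# ---------------------------------------------------------------------------
# Phase intervals
# ---------------------------------------------------------------------------

def phase_intervals(duration_s: float, annotations: list[SeizureAnnotation],
                    guard_pre_s: float = DEFAULT_GUARD_S,
                    guard_post_s: float = DEFAULT_GUARD_S) -> list[PhaseInterval]:
    """Ictal and no-seizure intervals of one record.

    Ictal intervals are the annotations themselves. No-seizure intervals
    are everything outside ``[onset - guard_pre, offset + guard_post)`` of
    every seizure, clipped to the record.
    """
    out = [PhaseInterval(ICTAL, a.onset_s, min(a.offset_s, duration_s)) for a in annotations]
    blocked = [(max(0.0, a.onset_s - guard_pre_s), min(duration_s, a.offset_s + guard_post_s))
               for a in annotations]
    blocked.sort()
    cursor = 0.0
    for b0, b1 in blocked:
        if b0 > cursor:
            out.append(PhaseInterval(NO_SEIZURE, cursor, b0))
        cursor = max(cursor, b1)
    if cursor < duration_s:
        out.append(PhaseInterval(NO_SEIZURE, cursor, duration_s))
    return out


# ---------------------------------------------------------------------------
# Map construction
# ---------------------------------------------------------------------------

def phase_mean_cwc(series: CWCSeries, intervals: list[PhaseInterval], phase: str) -> np.ndarray:
    """Mean CWC vector over the 1-s rows wholly inside the phase's intervals.

    Row ``t`` covers ``[t, t+1)`` seconds; NaN (degenerate) rows are
    skipped. Raises :class:`EmptyPhaseError` when nothing contributes.
    """
    T = series.n_windows
    mask = np.zeros(T, dtype=bool)
    for iv in intervals:
        if iv.phase != phase:
            continue
        lo = int(np.ceil(iv.start_s - 1e-9))
        hi = int(np.floor(iv.end_s + 1e-9))
        if hi > lo:
            mask[max(lo, 0):min(hi, T)] = True
    rows = series.matrix[mask]
    rows = rows[~np.isnan(rows).any(axis=1)]
    if rows.size == 0:
        raise EmptyPhaseError(f"no valid 1-s windows in phase {phase!r}")
    return rows.mean(axis=0)


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        # uninformative band: neither promotes nor demotes any channel
        return np.full_like(v, 0.5)
    return (v - lo) / (hi - lo)


def merge_bands(per_band: dict[str, np.ndarray]) -> np.ndarray:
    """Equal-weight band average of per-band min-max-normalized CWC vectors."""
    missing = set(BAND_NAMES) - set(per_band)
    if missing:
        raise SelectionError(f"missing bands: {sorted(missing)}")
    return np.mean([_minmax(np.asarray(per_band[b], dtype=float)) for b in BAND_NAMES], axis=0)


def average_records(maps: list[np.ndarray], phase: str = "") -> PhaseMap:
    """Element-wise mean of per-record merged maps, rescaled to [0, 1]."""
    if not maps:
        raise SelectionError("no per-record maps to average")
    mean = np.mean(np.asarray(maps, dtype=float), axis=0)
    if mean.max() == mean.min():
        raise SelectionError(f"degenerate averaged map for phase {phase!r}")
    return PhaseMap(phase=phase, values=_minmax(mean), n_records=len(maps))


def digitize(map_values: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Bit i = 1 iff values[i] > threshold (strictly)."""
    return np.asarray(map_values) > threshold


def xor_candidates(sct: SCTMap) -> tuple[set[int], set[int]]:
    """Channels dominant in exactly one phase (1-based numbers).

    Returns (no-seizure candidates, ictal candidates); channels set in
    both maps carry no phase-exclusive information and are dropped.
    """
    a_bits = sct.bits_no_seizure & ~sct.bits_ictal
    b_bits = sct.bits_ictal & ~sct.bits_no_seizure
    return (set(np.flatnonzero(a_bits) + 1), set(np.flatnonzero(b_bits) + 1))


# ---------------------------------------------------------------------------
# Correlation refinement
# ---------------------------------------------------------------------------

def mean_abs_pcc(decomps: BandDecomposition | list[BandDecomposition],
                 ch_a: int, ch_b: int) -> float:
    """Mean absolute Pearson correlation between two channels.

    Averages |r| over non-overlapping 1-s windows, the five bands, and
    (when a list is given) the records. Windows where either channel is
    constant are skipped; 1-based channel numbers.
    """
    if ch_a == ch_b:
        raise ValueError("channels must differ")
    if isinstance(decomps, BandDecomposition):
        decomps = [decomps]
    vals: list[float] = []
    ia, ib = ch_a - 1, ch_b - 1
    for dec in decomps:
        n = int(round(dec.fs))
        for band in BAND_NAMES:
            sig = dec.per_band[band]
            x, y = sig[ia], sig[ib]
            n_win = x.shape[0] // n
            xs = x[: n_win * n].reshape(n_win, n)
            ys = y[: n_win * n].reshape(n_win, n)
            xs = xs - xs.mean(axis=1, keepdims=True)
            ys = ys - ys.mean(axis=1, keepdims=True)
            sx = np.sqrt((xs**2).sum(axis=1))
            sy = np.sqrt((ys**2).sum(axis=1))
            ok = (sx > 0) & (sy > 0)
            if ok.any():
                r = (xs[ok] * ys[ok]).sum(axis=1) / (sx[ok] * sy[ok])
                vals.extend(np.abs(r))
    if not vals:
        raise SelectionError("no valid windows for correlation")
    return float(np.mean(vals))


def select_pair(candidates_a: set[int], candidates_b: set[int],
                decomps: BandDecomposition | list[BandDecomposition],
                phase_maps: dict[str, PhaseMap] | None = None,
                threshold: float = DEFAULT_THRESHOLD) -> ChannelPair:
    """Resolve candidate sets into one (no-seizure, ictal) channel pair.

    With candidates in both phases, the pair over A x B with the lowest
    mean absolute correlation wins (ties break toward lower channel
    numbers). Fallbacks when a set is empty: (1) one phase empty but the
    other holds >= 2 channels -> the two least-correlated channels of the
    nonempty set, ordered by channel number; (2) both empty -> lower the
    digitization threshold in 0.05 steps on the phase maps until two
    distinct candidates exist.
    """
    candidates_a, candidates_b = set(candidates_a), set(candidates_b)

    def _best(pairs: list[tuple[int, int]]) -> ChannelPair:
        scored = [(mean_abs_pcc(decomps, a, b), a, b) for a, b in pairs]
        rho, a, b = min(scored)
        return ChannelPair(channel_a=a, channel_b=b, rho_bar=rho)

    if candidates_a and candidates_b:
        pairs = [(a, b) for a, b in itertools.product(sorted(candidates_a), sorted(candidates_b))
                 if a != b]
        if pairs:
            return _best(pairs)
        candidates_a, candidates_b = set(), set()  # identical singleton sets

    lone = candidates_a or candidates_b
    if len(lone) >= 2:
        pairs = [(min(a, b), max(a, b)) for a, b in itertools.combinations(sorted(lone), 2)]
        return _best(pairs)

    if phase_maps is not None:
        th = threshold
        while th > 0.0:
            th = round(th - 0.05, 10)
            sct = SCTMap(
                bits_ictal=digitize(phase_maps[ICTAL].values, th),
                bits_no_seizure=digitize(phase_maps[NO_SEIZURE].values, th),
            )
            a_set, b_set = xor_candidates(sct)
            a_set |= candidates_a
            b_set |= candidates_b
            if len(a_set | b_set) >= 2:
                return select_pair(a_set, b_set, decomps, phase_maps=None)
    raise SelectionError("fewer than two distinct candidate channels after fallbacks")


def majority_vote(pairs: list[ChannelPair]) -> ChannelPair:
    """Most frequent (A, B) pair across folds.

    Ties break toward lower mean rho_bar, then lexicographically lower
    (A, B).
    """
    if not pairs:
        raise SelectionError("no pairs to vote over")
    groups: dict[tuple[int, int], list[ChannelPair]] = {}
    for p in pairs:
        groups.setdefault((p.channel_a, p.channel_b), []).append(p)
    best_key = min(
        groups,
        key=lambda k: (-len(groups[k]), float(np.mean([p.rho_bar for p in groups[k]])), k),
    )
    members = groups[best_key]
    return ChannelPair(best_key[0], best_key[1],
                       rho_bar=float(np.mean([p.rho_bar for p in members])))


# ---------------------------------------------------------------------------
# Record-level pipeline
# ---------------------------------------------------------------------------

@dataclass
class RecordPhaseStats:
    """Cached per-record inputs to selection: per-band phase means and the
    band decomposition (for correlations). Computed once, reused across
    leave-one-record-out folds."""

    record_id: str
    per_band_ictal: dict[str, np.ndarray] | None
    per_band_no_seizure: dict[str, np.ndarray] | None
    decomp: BandDecomposition


def record_phase_stats(record: EEGRecord, annotations: list[SeizureAnnotation],
                       guard_s: float = DEFAULT_GUARD_S,
                       preprocessed: bool = False,
                       powerline_hz: float = 60.0,
                       include_seizure_free: bool = False) -> RecordPhaseStats:
    """Compute one record's per-band phase-mean CWC vectors.

    ``preprocessed`` marks a record already notch-filtered and z-scored.
    Records without annotated seizures get ``None`` phase vectors by
    default (the phase maps are built from seizure records only) but
    still carry their band decomposition; ``include_seizure_free`` lets
    such records contribute their whole duration to the no-seizure map.
    """
    rec = record if preprocessed else preprocess_record(record, powerline_hz=powerline_hz)
    decomp = band_decompose(rec)
    intervals = phase_intervals(rec.duration_s, annotations,
                                guard_pre_s=guard_s, guard_post_s=guard_s)
    has_seizure = bool(annotations)
    want_ns = has_seizure or include_seizure_free
    ictal_maps: dict[str, np.ndarray] = {}
    ns_maps: dict[str, np.ndarray] = {}
    if has_seizure or want_ns:
        for band in BAND_NAMES:
            series = cwc_series(decomp.per_band[band], rec.fs, band=band,
                                record_id=rec.record_id)
            if has_seizure:
                ictal_maps[band] = phase_mean_cwc(series, intervals, ICTAL)
            if want_ns:
                ns_maps[band] = phase_mean_cwc(series, intervals, NO_SEIZURE)
    return RecordPhaseStats(
        record_id=rec.record_id,
        per_band_ictal=ictal_maps if has_seizure else None,
        per_band_no_seizure=ns_maps if want_ns else None,
        decomp=decomp,
    )


@dataclass
class SelectionResult:
    pair: ChannelPair
    phase_maps: dict[str, PhaseMap]
    sct: SCTMap
    candidates_a: set[int]
    candidates_b: set[int]


def select_from_stats(stats: list[RecordPhaseStats],
                      threshold: float = DEFAULT_THRESHOLD) -> SelectionResult:
    """Run steps 3-5 (record averaging through pair refinement) on cached
    per-record statistics."""
    seizure_stats = [s for s in stats if s.per_band_ictal is not None]
    ns_stats = [s for s in stats if s.per_band_no_seizure is not None]
    if not seizure_stats:
        raise SelectionError("no seizure-containing record available for selection")
    merged_ictal = [merge_bands(s.per_band_ictal) for s in seizure_stats]
    merged_ns = [merge_bands(s.per_band_no_seizure) for s in ns_stats]
    maps = {
        ICTAL: average_records(merged_ictal, phase=ICTAL),
        NO_SEIZURE: average_records(merged_ns, phase=NO_SEIZURE),
    }
    sct = SCTMap(
        bits_ictal=digitize(maps[ICTAL].values, threshold),
        bits_no_seizure=digitize(maps[NO_SEIZURE].values, threshold),
    )
    cand_a, cand_b = xor_candidates(sct)
    decomps = [s.decomp for s in seizure_stats]
    pair = select_pair(cand_a, cand_b, decomps, phase_maps=maps, threshold=threshold)
    return SelectionResult(pair=pair, phase_maps=maps, sct=sct,
                           candidates_a=cand_a, candidates_b=cand_b)


def select_with_loro(stats: list[RecordPhaseStats],
                     threshold: float = DEFAULT_THRESHOLD
                     ) -> tuple[ChannelPair, list[ChannelPair]]:
    """Leave-one-record-out selection with majority voting.

    One selection per fold (each record excluded once, provided at least
    one seizure record remains); the most frequent pair wins. This is the
    canonical entry point feeding the classifier, so the chosen pair never
    depends on any single held-out record.
    """
    if len(stats) < 2:
        result = select_from_stats(stats, threshold=threshold)
        return result.pair, [result.pair]
    fold_pairs: list[ChannelPair] = []
    for leave_out in range(len(stats)):
        subset = [s for i, s in enumerate(stats) if i != leave_out]
        if not any(s.per_band_ictal is not None for s in subset):
            continue
        fold_pairs.append(select_from_stats(subset, threshold=threshold).pair)
    return majority_vote(fold_pairs), fold_pairs
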