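"""Reading and writing EEG recordings and seizure annotations.

Recordings travel as EDF (European Data Format) files with the 21 bipolar
10-20 derivations; annotations as plain-text per-record summary blocks in
the dialect of the CHB-MIT scalp EEG corpus ("File Name: ...",
"Seizure Start Time: N seconds"). Reading goes through :mod:`mne`; EDF
writing is a minimal single-rate 16-bit writer sufficient for fixtures and
synthetic patients.

Time is real-valued seconds from record start; all intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .montage import ChannelScheme, DEFAULT_SCHEME, N_CHANNELS, normalize_label


class DataIOError(Exception):
    """Base error for recording/annotation I/O."""


class MissingChannelError(DataIOError):
    """A canonical bipolar derivation could not be resolved in the file."""


class AnnotationParseError(DataIOError):
    """Malformed annotation text; carries the offending line number."""


@dataclass
class SeizureAnnotation:
    """One annotated ictal event, ``[onset_s, offset_s)`` seconds from record start."""

    record_id: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.onset_s < self.offset_s):
            raise ValueError(
                f"invalid annotation for {self.record_id}: "
                f"onset {self.onset_s} must be >= 0 and < offset {self.offset_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class EEGRecord:
    """One multichannel recording with rows in canonical montage order."""

    patient_id: str
    record_id: str
    fs: float
    samples: np.ndarray  # (21, n_samples), microvolt-scale floats
    scheme: ChannelScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[0] != N_CHANNELS:
            raise ValueError(
                f"samples must be ({N_CHANNELS}, T), got {self.samples.shape}"
            )
        if self.fs <= 160.0:
            # analysis bands extend to 80 Hz; anything at or below 2*80 Hz
            # cannot represent them
            raise ValueError(f"sampling rate {self.fs} Hz too low for 80 Hz analysis bands")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, samples: np.ndarray) -> "EEGRecord":
        return EEGRecord(self.patient_id, self.record_id, self.fs, samples, self.scheme)


# ---------------------------------------------------------------------------
# EDF reading (via mne) and a minimal EDF writer
# ---------------------------------------------------------------------------

def read_record(path: str | Path, scheme: ChannelScheme = DEFAULT_SCHEME,
                patient_id: str | None = None) -> EEGRecord:
    """Read an EDF file and return a record in canonical channel order.

    All 21 scheme labels must be resolvable among the file's signal labels
    (matching is case/punctuation-insensitive); extra signals are dropped
    and duplicate labels keep their first occurrence. Rows are reordered to
    the canonical scheme regardless of on-disk order.
    """
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne error text varies
        raise DataIOError(f"could not read EDF file {path}: {exc}") from exc

    by_key: dict[str, int] = {}
    for i, name in enumerate(raw.ch_names):
        key = normalize_label(name)
        by_key.setdefault(key, i)  # keep first occurrence of duplicates

    rows = []
    for label in scheme.labels:
        key = normalize_label(label)
        if key not in by_key:
            raise MissingChannelError(
                f"channel {label!r} not found in {path.name} "
                f"(available: {raw.ch_names})"
            )
        rows.append(by_key[key])

    data = raw.get_data(picks=rows) * 1e6  # mne returns volts; keep microvolts
    record_id = path.stem
    if patient_id is None:
        patient_id = record_id.split("_")[0]
    return EEGRecord(patient_id, record_id, float(raw.info["sfreq"]), data, scheme)


def write_edf(path: str | Path, record: EEGRecord, physical_range_uv: float = 200.0) -> Path:
    """Write a record as a minimal EDF file (one sampling rate, 16-bit).

    The duration must be a whole number of seconds (EDF data records here
    are 1 s long). Samples are clipped to ``+-physical_range_uv`` and
    quantized to the 16-bit digital range, the usual EDF precision.
    """
    path = Path(path)
    fs = int(round(record.fs))
    if abs(fs - record.fs) > 1e-9:
        raise DataIOError("EDF writer requires an integer sampling rate")
    n_samples = record.n_samples
    if n_samples % fs != 0:
        raise DataIOError("EDF writer requires a whole number of seconds of data")
    n_records = n_samples // fs
    nsig = record.samples.shape[0]

    def _field(values, width) -> bytes:
        out = b""
        for v in values:
            s = str(v).encode("ascii")[:width]
            out += s.ljust(width)
        return out

    header = b"0".ljust(8)
    header += record.patient_id.encode("ascii", "replace")[:80].ljust(80)
    header += f"Startdate 01-JAN-2000 {record.record_id}".encode("ascii", "replace")[:80].ljust(80)
    header += b"01.01.00" + b"00.00.00"
    header_bytes = 256 + 256 * nsig
    header += _field([header_bytes], 8)
    header += b"".ljust(44)
    header += _field([n_records], 8)
    header += _field([1], 8)  # 1 s per data record
    header += _field([nsig], 4)
    header += _field(record.scheme.labels, 16)
    header += _field([""] * nsig, 80)      # transducer
    header += _field(["uV"] * nsig, 8)
    header += _field([-physical_range_uv] * nsig, 8)
    header += _field([physical_range_uv] * nsig, 8)
    header += _field([-32768] * nsig, 8)
    header += _field([32767] * nsig, 8)
    header += _field([""] * nsig, 80)      # prefiltering
    header += _field([fs] * nsig, 8)
    header += _field([""] * nsig, 32)
    assert len(header) == header_bytes

    scale = 65535.0 / (2.0 * physical_range_uv)
    digital = np.clip(
        np.round((record.samples + physical_range_uv) * scale - 32768.0),
        -32768, 32767,
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())
    return path


# ---------------------------------------------------------------------------
# CHB-MIT-style annotation text
# ---------------------------------------------------------------------------

_FILE_RE = re.compile(r"^File Name:\s*(\S+?)(?:\.edf)?\s*$", re.IGNORECASE)
_NSEIZ_RE = re.compile(r"^Number of Seizures in File:\s*(\d+)\s*$", re.IGNORECASE)
# accepts both "Seizure Start Time:" and "Seizure 2 Start Time:" dialects
_START_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+Start Time:\s*([\d.]+)\s*seconds?\s*$", re.IGNORECASE)
_END_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+End Time:\s*([\d.]+)\s*seconds?\s*$", re.IGNORECASE)


def parse_annotations(text: str) -> list[SeizureAnnotation]:
    """Parse CHB-MIT summary text into validated, sorted annotations.

    Returns one :class:`SeizureAnnotation` per (start, end) pair, sorted by
    onset within each record. Records declaring zero seizures contribute
    nothing. A start without a matching end (or end <= start) raises
    :class:`AnnotationParseError` naming the line.
    """
    annotations: list[SeizureAnnotation] = []
    record_id: str | None = None
    pending_start: float | None = None
    pending_line = 0
    per_record: dict[str, list[SeizureAnnotation]] = {}

    def _flush_pending(lineno: int) -> None:
        if pending_start is not None:
            raise AnnotationParseError(
                f"line {lineno}: seizure start at line {pending_line} has no end time"
            )

    for lineno, raw_line in enumerate(text.splitlines(), start=1):
        line = raw_line.strip()
        if not line:
            continue
        m = _FILE_RE.match(line)
        if m:
            _flush_pending(lineno)
            record_id = m.group(1)
            per_record.setdefault(record_id, [])
            continue
        m = _START_RE.match(line)
        if m:
            if record_id is None:
                raise AnnotationParseError(f"line {lineno}: seizure time before any 'File Name:'")
            _flush_pending(lineno)
            pending_start = float(m.group(1))
            pending_line = lineno
            continue
        m = _END_RE.match(line)
        if m:
            if record_id is None:
                raise AnnotationParseError(f"line {lineno}: seizure time before any 'File Name:'")
            if pending_start is None:
                raise AnnotationParseError(f"line {lineno}: seizure end without a start time")
            end = float(m.group(1))
            if end <= pending_start:
                raise AnnotationParseError(
                    f"line {lineno}: seizure end {end} s <= start {pending_start} s"
                )
            per_record[record_id].append(SeizureAnnotation(record_id, pending_start, end))
            pending_start = None
            continue
        # other summary lines (times, channel lists, counts) are ignored,
        # but a line that looks like a seizure time and failed to parse is not
        if line.lower().startswith("seizure"):
            raise AnnotationParseError(f"line {lineno}: malformed seizure line: {line!r}")
    _flush_pending(lineno if text.strip() else 0)

    for rid, anns in per_record.items():
        anns.sort(key=lambda a: a.onset_s)
        for prev, nxt in zip(anns, anns[1:]):
            if nxt.onset_s < prev.offset_s:
                raise AnnotationParseError(
                    f"overlapping seizure annotations in record {rid}"
                )
        annotations.extend(anns)
    return annotations


def annotations_by_record(annotations: list[SeizureAnnotation]) -> dict[str, list[SeizureAnnotation]]:
    """Group annotations per record id, each list sorted by onset."""
    out: dict[str, list[SeizureAnnotation]] = {}
    for a in annotations:
        out.setdefault(a.record_id, []).append(a)
    for anns in out.values():
        anns.sort(key=lambda a: a.onset_s)
    return out


def write_summary(path: str | Path, records: list[EEGRecord],
                  annotations: dict[str, list[SeizureAnnotation]]) -> Path:
    """Write a CHB-MIT-style summary text for a set of records."""
    lines: list[str] = []
    for rec in records:
        anns = annotations.get(rec.record_id, [])
        lines.append(f"File Name: {rec.record_id}.edf")
        lines.append(f"Number of Seizures in File: {len(anns)}")
        for i, a in enumerate(sorted(anns, key=lambda a: a.onset_s), start=1):
            tag = f"Seizure {i} " if len(anns) > 1 else "Seizure "
            lines.append(f"{tag}Start Time: {a.onset_s:g} seconds")
            lines.append(f"{tag}End Time: {a.offset_s:g} seconds")
        lines.append("")
    path = Path(path)
    path.write_text("\n".join(lines))
    return path
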