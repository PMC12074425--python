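"""Signal conditioning: powerline notch, z-scoring, clinical-band decomposition.

All filters are second-order Butterworth designs applied forward-backward
(zero phase), independently per channel. The processing order is fixed:
notch, then per-channel z-score over the whole record, then band-pass
decomposition into the five clinical bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .data_io import EEGRecord


class PreprocessError(Exception):
    pass


class DegenerateChannelError(PreprocessError):
    """A channel is constant, so it cannot be z-scored."""


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float


#: The five clinical EEG bands, in canonical low-to-high order.
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 35.0),
    BandDefinition("gamma", 35.0, 80.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in BANDS)
BAND_EDGES: dict[str, tuple[float, float]] = {b.name: (b.low_hz, b.high_hz) for b in BANDS}


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in seconds."""

    length_s: float
    stride_s: float

    def __post_init__(self) -> None:
        if not (0 < self.stride_s <= self.length_s):
            raise ValueError("require 0 < stride_s <= length_s")


@dataclass
class BandDecomposition:
    """Per-band filtered copies of one record's samples matrix."""

    record_id: str
    fs: float
    per_band: dict[str, np.ndarray]  # band name -> (21, T)

    def __post_init__(self) -> None:
        missing = set(BAND_NAMES) - set(self.per_band)
        if missing:
            raise ValueError(f"missing bands: {sorted(missing)}")


def _filtfilt(b: np.ndarray, a: np.ndarray, x: np.ndarray) -> np.ndarray:
    return signal.filtfilt(b, a, x, axis=-1)


def notch_powerline(record: EEGRecord, center_hz: float = 60.0,
                    width_hz: float = 1.0) -> EEGRecord:
    """Remove the powerline component with a zero-phase band-stop.

    ``width_hz`` is the total stop-band width, so the default rejects
    ``[center-0.5, center+0.5]`` Hz with a second-order Butterworth design.
    """
    nyq = record.fs / 2.0
    if center_hz + width_hz / 2.0 >= nyq:
        raise PreprocessError(
            f"notch at {center_hz} Hz does not fit below Nyquist ({nyq} Hz)"
        )
    b, a = signal.butter(2, [center_hz - width_hz / 2.0, center_hz + width_hz / 2.0],
                         btype="bandstop", fs=record.fs)
    return record.copy_with(_filtfilt(b, a, record.samples))


def zscore(record: EEGRecord) -> EEGRecord:
    """Standardize each channel to zero mean and unit standard deviation."""
    mean = record.samples.mean(axis=1, keepdims=True)
    sd = record.samples.std(axis=1, keepdims=True)
    flat = np.flatnonzero(sd[:, 0] == 0.0)
    if flat.size:
        labels = [record.scheme.label(int(i) + 1) for i in flat]
        raise DegenerateChannelError(
            f"constant channel(s) cannot be z-scored: {labels}"
        )
    return record.copy_with((record.samples - mean) / sd)


def band_decompose(record: EEGRecord) -> BandDecomposition:
    """Band-pass the record into the five clinical bands (zero phase).

    Expects an already notch-filtered, z-scored record; the decomposition
    itself is linear and does not enforce that.
    """
    nyq = record.fs / 2.0
    if BANDS[-1].high_hz >= nyq:
        raise PreprocessError(
            f"sampling rate {record.fs} Hz too low for the {BANDS[-1].name} band"
        )
    per_band = {}
    for band in BANDS:
        b, a = signal.butter(2, [band.low_hz, band.high_hz], btype="bandpass", fs=record.fs)
        per_band[band.name] = _filtfilt(b, a, record.samples)
    return BandDecomposition(record.record_id, record.fs, per_band)


def preprocess_record(record: EEGRecord, powerline_hz: float = 60.0) -> EEGRecord:
    """Notch + z-score, the broadband conditioning shared by all consumers."""
    return zscore(notch_powerline(record, center_hz=powerline_hz))


def make_windows(sig: np.ndarray, fs: float, spec: WindowSpec
                 ) -> list[tuple[float, np.ndarray]]:
    """Cut a (channels, T) signal into windows of ``spec.length_s`` every
    ``spec.stride_s`` seconds.

    Returns ``(start_s, window)`` pairs at starts 0, stride, 2*stride, ...;
    a trailing partial window is dropped. A signal shorter than one window
    yields an empty list.
    """
    sig = np.atleast_2d(np.asarray(sig))
    n = sig.shape[1]
    win = int(round(spec.length_s * fs))
    hop = int(round(spec.stride_s * fs))
    out = []
    start = 0
    while start + win <= n:
        out.append((start / fs, sig[:, start:start + win]))
        start += hop
    return out
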