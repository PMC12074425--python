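"""Synthetic scalp-EEG patients with planted, channel-localized seizures.

The generator emulates the statistics of a clinical scalp-EEG corpus well
enough to exercise the whole pipeline without any download: 21 bipolar
channels at 256 Hz, records of minutes, rare annotated ictal events of
10-60 s. Each channel carries 1/f ("pink") background noise plus a
spatially correlated low-rank component shared across channels (shared
mixing is redrawn per record, with equal loading norm per channel, so PCA
faces realistic cross-channel correlation within each record without any
channel being systematically dominant across the patient).

Channels additionally carry a stable per-patient spatial amplitude
profile (lognormal channel gains, identical across bands and records).
Such persistent amplitude structure elevates the same channels in *both*
seizure phases, which is exactly what the selection method's XOR step
cancels; without it the min-max normalization would merely stretch
estimation noise to the full [0, 1] range.

Two channel-localized signatures are planted:

* during every annotated seizure, channel ``ictal_channel`` (b*) receives
  a broadband discharge spanning the beta-gamma range (13-80 Hz), raising
  band power by the factor ``ictal_gain`` (its two montage neighbours get
  a reduced dose); ictal discharges are spectrally broad, which is why
  the boost covers both high-frequency bands, with ``ictal_band`` naming
  the primary one;
* during no-seizure stretches, channel ``baseline_channel`` (a*) carries
  a posterior-dominant-rhythm-like signature centred on alpha with power
  factor ``baseline_gain``: like physiological alpha it is non-sinusoidal,
  with a first harmonic in the beta range and a slow amplitude-modulation
  component in theta, both at reduced amplitude.

Gains are power multipliers of the channel's own band-limited background,
so a gain of 1 plants nothing (the negative control). Everything is drawn
from one seeded generator: the same seed reproduces records and
annotations byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from .data_io import EEGRecord, SeizureAnnotation, write_edf, write_summary
from .montage import DEFAULT_SCHEME, N_CHANNELS
from .preprocess import BAND_EDGES


class SyntheticError(Exception):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of one synthetic patient."""

    n_records: int = 4
    record_len_s: float = 600.0
    fs: float = 256.0
    seizures_per_record: int = 1
    seizure_len_s: tuple[float, float] = (10.0, 60.0)
    ictal_channel: int = 9        # F8-T8, 1-based canonical number
    baseline_channel: int = 19    # P3-O1
    ictal_band: str = "gamma"
    ictal_gain: float = 8.0       # band-power multiplier during seizures
    baseline_band: str = "alpha"
    baseline_gain: float = 8.0    # band-power multiplier outside seizures
    guard_s: float = 60.0         # placement margin; selection uses the same guard
    background_uv: float = 30.0   # background standard deviation, microvolts
    shared_fraction: float = 0.25 # variance share of the spatially shared component
    profile_spread: float = 0.1   # sd of the log of the stable channel-amplitude profile
    harmonic_fraction: float = 0.6  # amplitude of the alpha rhythm's beta harmonic
    theta_fraction: float = 0.5   # amplitude of the alpha rhythm's slow (theta) component
    neighbour_gain_fraction: float = 0.3  # amplitude fraction leaked to b* neighbours
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ictal_channel == self.baseline_channel:
            raise ValueError("planted channels must differ")
        if self.ictal_gain < 1 or self.baseline_gain < 1:
            raise ValueError("gains are power multipliers and must be >= 1")
        if self.ictal_band not in ("beta", "gamma"):
            raise ValueError("ictal_band must be beta or gamma")


@dataclass
class SyntheticPatient:
    records: list[EEGRecord]
    annotations: dict[str, list[SeizureAnnotation]]
    config: SyntheticConfig

    @property
    def planted_pair(self) -> tuple[int, int]:
        """(no-seizure channel a*, ictal channel b*), 1-based."""
        return (self.config.baseline_channel, self.config.ictal_channel)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Rows of 1/f-amplitude noise, unit variance."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    weights = np.ones_like(freqs)
    weights[1:] = 1.0 / np.sqrt(freqs[1:])
    weights[0] = 0.0
    out = np.fft.irfft(spec * weights, n=n, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-variance noise band-limited to ``band`` Hz."""
    b, a = signal.butter(2, band, btype="bandpass", fs=fs)
    x = signal.filtfilt(b, a, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd else x


def _place_seizures(rng: np.random.Generator, cfg: SyntheticConfig) -> list[tuple[float, float]]:
    """Seizure intervals with >= guard margins at the edges and > 2*guard apart."""
    margin = cfg.guard_s
    intervals: list[tuple[float, float]] = []
    for _ in range(cfg.seizures_per_record):
        for _attempt in range(200):
            # whole-second times, matching clinical annotation precision
            length = float(rng.integers(int(cfg.seizure_len_s[0]), int(cfg.seizure_len_s[1]) + 1))
            lo, hi = margin, cfg.record_len_s - margin - length
            if hi <= lo:
                raise SyntheticError("record too short for the requested seizures")
            onset = float(rng.integers(int(np.ceil(lo)), int(np.floor(hi)) + 1))
            ok = all(
                onset > off + 2 * cfg.guard_s or onset + length < on - 2 * cfg.guard_s
                for on, off in intervals
            )
            if ok:
                intervals.append((onset, onset + length))
                break
        else:
            raise SyntheticError("could not place non-overlapping seizures")
    return sorted(intervals)


def _band_sigma(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    b, a = signal.butter(2, band, btype="bandpass", fs=fs)
    return float(signal.filtfilt(b, a, x).std())


def generate_patient(cfg: SyntheticConfig = SyntheticConfig(),
                     patient_id: str = "syn01") -> SyntheticPatient:
    """Generate one patient's records, annotations, and planted truth."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.record_len_s * cfg.fs))
    n_shared = 8

    sigma_shared = cfg.background_uv * np.sqrt(cfg.shared_fraction)
    sigma_priv = cfg.background_uv * np.sqrt(1.0 - cfg.shared_fraction)
    # ictal discharges span the full high-frequency range regardless of the
    # primary band; the alpha rhythm carries a first harmonic in beta
    ictal_span = (BAND_EDGES["beta"][0], BAND_EDGES["gamma"][1])
    alpha_edges = BAND_EDGES[cfg.baseline_band]
    harmonic_edges = (2 * alpha_edges[0], 2 * alpha_edges[1])
    theta_edges = (alpha_edges[0] / 2, alpha_edges[1] / 2)
    i_b = cfg.ictal_channel - 1
    i_a = cfg.baseline_channel - 1
    # stable per-patient spatial amplitude profile (see module docstring)
    profile = np.exp(cfg.profile_spread * rng.standard_normal(N_CHANNELS))

    records: list[EEGRecord] = []
    annotations: dict[str, list[SeizureAnnotation]] = {}
    for r in range(cfg.n_records):
        record_id = f"{patient_id}_{r + 1:02d}"
        # per-record mixing with equal loading norm per channel: the spatial
        # correlation is real within a record but no channel is
        # systematically favoured across records
        mixing = rng.standard_normal((N_CHANNELS, n_shared))
        mixing /= np.linalg.norm(mixing, axis=1, keepdims=True)
        shared = sigma_shared * (mixing @ _pink_noise(rng, (n_shared, n)))
        private = sigma_priv * _pink_noise(rng, (N_CHANNELS, n))
        data = (shared + private) * profile[:, np.newaxis]

        seiz = _place_seizures(rng, cfg)
        anns = [SeizureAnnotation(record_id, on, off) for on, off in seiz]

        # planted ictal signature: broadband high-frequency discharge on b*
        # (and a reduced dose on its montage neighbours)
        amp_i = np.sqrt(max(cfg.ictal_gain - 1.0, 0.0)) * _band_sigma(data[i_b], cfg.fs, ictal_span)
        if amp_i > 0:
            for on, off in seiz:
                s0, s1 = int(round(on * cfg.fs)), int(round(off * cfg.fs))
                burst = _band_noise(rng, s1 - s0, cfg.fs, ictal_span)
                taper = signal.windows.tukey(s1 - s0, alpha=0.2)
                burst = amp_i * burst * taper
                data[i_b, s0:s1] += burst
                for nb in (i_b - 1, i_b + 1):
                    if 0 <= nb < N_CHANNELS:
                        data[nb, s0:s1] += cfg.neighbour_gain_fraction * burst

        # planted no-seizure signature: alpha rhythm + beta harmonic on a*,
        # active outside the seizures and a half-guard margin around them
        amp_a = np.sqrt(max(cfg.baseline_gain - 1.0, 0.0)) * _band_sigma(data[i_a], cfg.fs, alpha_edges)
        if amp_a > 0:
            rhythm = (_band_noise(rng, n, cfg.fs, alpha_edges)
                      + cfg.harmonic_fraction * _band_noise(rng, n, cfg.fs, harmonic_edges)
                      + cfg.theta_fraction * _band_noise(rng, n, cfg.fs, theta_edges))
            mask = np.ones(n)
            for on, off in seiz:
                s0 = int(round(max(0.0, on - cfg.guard_s / 2) * cfg.fs))
                s1 = int(round(min(cfg.record_len_s, off + cfg.guard_s / 2) * cfg.fs))
                mask[s0:s1] = 0.0
            data[i_a] += amp_a * rhythm * mask

        records.append(EEGRecord(patient_id, record_id, cfg.fs, data, DEFAULT_SCHEME))
        annotations[record_id] = anns
    return SyntheticPatient(records=records, annotations=annotations, config=cfg)


def write_fixture(patient: SyntheticPatient, out_dir: str | Path) -> Path:
    """Write a CHB-MIT-style directory: one EDF per record + summary text."""
    if not patient.records:
        raise SyntheticError("no records to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in patient.records:
        write_edf(out_dir / f"{rec.record_id}.edf", rec)
    pid = patient.records[0].patient_id
    write_summary(out_dir / f"{pid}-summary.txt", patient.records, patient.annotations)
    return out_dir
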