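"""Canonical bipolar 10-20 montage used throughout the package.

Scalp EEG channels are bipolar derivations (voltage differences between
adjacent electrodes of the international 10-20 placement system). The
canonical ordering numbers the 21 derivations from 1 (left frontal) to 21
(right occipital); every in-memory record keeps its rows in this order so
that channel indices are comparable across recordings and patients.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: Canonical 1-based numbering of the 21 bipolar derivations.
CANONICAL_LABELS: tuple[str, ...] = (
    "Fp1-F7",   # 1  left frontal
    "Fp1-F3",   # 2
    "Fp2-F8",   # 3
    "Fp2-F4",   # 4
    "F7-T7",    # 5
    "F3-C3",    # 6
    "Fz-Cz",    # 7
    "F4-C4",    # 8
    "F8-T8",    # 9
    "T7-FT9",   # 10
    "T7-P7",    # 11
    "C3-P3",    # 12
    "Cz-Pz",    # 13
    "C4-P4",    # 14
    "T8-P8",    # 15
    "FT10-T8",  # 16
    "FT9-FT10", # 17
    "P7-O1",    # 18
    "P3-O1",    # 19
    "P4-O2",    # 20
    "P8-O2",    # 21  right occipital
)

N_CHANNELS = len(CANONICAL_LABELS)

#: Four fixed temporal derivations used by the baseline detector configuration.
TEMPORAL4_LABELS: tuple[str, ...] = ("F7-T7", "T7-P7", "F8-T8", "T8-P8")


def normalize_label(label: str) -> str:
    """Normalization key for channel-label matching.

    Recorded EDF files vary in casing, whitespace and punctuation
    ("FP1-F7", "Fp1-F7 ", "FP1 - F7" all denote the same derivation);
    matching keeps alphanumerics only, uppercased.
    """
    return re.sub(r"[^A-Za-z0-9]", "", label).upper()


@dataclass(frozen=True)
class ChannelScheme:
    """Ordered mapping from canonical channel number (1..21) to bipolar label."""

    labels: tuple[str, ...] = CANONICAL_LABELS

    def __post_init__(self) -> None:
        if len(self.labels) != N_CHANNELS:
            raise ValueError(f"scheme must have {N_CHANNELS} labels, got {len(self.labels)}")
        keys = [normalize_label(lb) for lb in self.labels]
        if len(set(keys)) != len(keys):
            raise ValueError("scheme labels are not unique")

    @property
    def index_to_label(self) -> dict[int, str]:
        return {i + 1: lb for i, lb in enumerate(self.labels)}

    def label(self, number: int) -> str:
        """Label of the 1-based canonical channel ``number``."""
        return self.labels[number - 1]

    def number(self, label: str) -> int:
        """1-based canonical number of ``label`` (normalization-insensitive)."""
        key = normalize_label(label)
        for i, lb in enumerate(self.labels):
            if normalize_label(lb) == key:
                return i + 1
        raise KeyError(f"unknown bipolar label: {label!r}")

    def row(self, label: str) -> int:
        """0-based row index of ``label`` in a canonical samples matrix."""
        return self.number(label) - 1


DEFAULT_SCHEME = ChannelScheme()
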