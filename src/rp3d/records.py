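"""Core record containers shared across the pipeline.

Amplitudes are millivolts end-to-end; sampling rates are Hz. A 12-lead
record always carries the canonical lead order (I, II, III, aVR, aVL,
aVF, V1..V6); a derived vectorcardiogram carries (Vx, Vy, Vz).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RhythmClass",
    "ECGRecord",
    "VCGRecord",
    "STANDARD_12_LEADS",
    "VCG_LEADS",
    "canonical_lead_name",
]

#: Canonical 12-lead order: limb leads first, then chest leads.
STANDARD_12_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

VCG_LEADS: tuple[str, ...] = ("Vx", "Vy", "Vz")

# Common aliases seen in exported ECG files, keyed lower-case.
_LEAD_ALIASES = {
    "d1": "I", "di": "I", "lead1": "I", "leadi": "I",
    "d2": "II", "dii": "II", "lead2": "II", "leadii": "II",
    "d3": "III", "diii": "III", "lead3": "III", "leadiii": "III",
}


def canonical_lead_name(name: str) -> str:
    """Map a lead label to its canonical spelling, case-insensitively.

    "AVR" -> "aVR", "v3" -> "V3", "D1"/"DI" -> "I". Unknown labels are
    returned stripped but otherwise untouched (e.g. "Vx").
    """
    key = name.strip()
    low = key.lower()
    if low in _LEAD_ALIASES:
        return _LEAD_ALIASES[low]
    for canon in STANDARD_12_LEADS + VCG_LEADS:
        if low == canon.lower():
            return canon
    return key


class RhythmClass(enum.Enum):
    """The four rhythm classes, in fixed order.

    The ordering defines label indices and confusion-matrix axes:
    normal sinus rhythm, atrial fibrillation, left bundle branch
    block, first-degree atrioventricular block.
    """

    NSR = 0
    AF = 1
    LBBB = 2
    IAVB = 3

    @property
    def index(self) -> int:
        return self.value

    @classmethod
    def from_name(cls, name: str) -> "RhythmClass":
        key = name.strip().upper().replace("-", "").replace("_", "")
        for member in cls:
            if member.name == key:
                return member
        raise ValueError(f"unknown rhythm class {name!r}; expected one of "
                         f"{[m.name for m in cls]}")


CLASS_ORDER: tuple[RhythmClass, ...] = tuple(RhythmClass)


def _validate_signals(signals: np.ndarray, lead_names: Sequence[str], fs: float) -> np.ndarray:
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2:
        raise ValueError(f"signals must be 2-D [n_leads x n_samples], got shape {signals.shape}")
    if signals.shape[0] != len(lead_names):
        raise ValueError(
            f"{signals.shape[0]} signal rows but {len(lead_names)} lead names")
    if not np.all(np.isfinite(signals)):
        raise ValueError("signals contain NaN or Inf samples")
    if not fs > 0:
        raise ValueError(f"sampling frequency must be > 0, got {fs}")
    return signals


@dataclass
class ECGRecord:
    """One subject's multi-lead ECG: signals in mV plus labels.

    ``meta`` carries generator annotations (RR series, PR interval,
    QRS width, P-wave flag) when the record is synthetic.
    """

    record_id: str
    signals: np.ndarray          # [n_leads, n_samples], mV
    lead_names: tuple[str, ...]
    fs: float
    labels: frozenset[RhythmClass] = field(default_factory=frozenset)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lead_names = tuple(canonical_lead_name(n) for n in self.lead_names)
        self.signals = _validate_signals(self.signals, self.lead_names, self.fs)
        self.labels = frozenset(self.labels)

    @property
    def n_leads(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's samples by canonical name."""
        name = canonical_lead_name(name)
        try:
            idx = self.lead_names.index(name)
        except ValueError:
            raise KeyError(f"record {self.record_id!r} has no lead {name!r}; "
                           f"available: {self.lead_names}") from None
        return self.signals[idx]


@dataclass
class VCGRecord(ECGRecord):
    """Derived Frank-lead vectorcardiogram (Vx, Vy, Vz)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.lead_names != VCG_LEADS:
            raise ValueError(f"VCG records must carry leads {VCG_LEADS}, got {self.lead_names}")
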