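"""Frank vectorcardiogram synthesis from the 12-lead ECG.

The Frank leads span the right-left (Vx), head-feet (Vy) and
anterior-posterior (Vz) axes. They are obtained from the eight
electrically independent surface leads (I, II, V1..V6) by a fixed
linear regression map; the default coefficients below are the
published Frank-synthesis values, with an outer sign flip on Vx and
Vz. The lead-I coefficient of Vy is -0.227 (regression matrices of
this family have sub-unit entries; a coefficient sanity check rejects
wildly out-of-range values unless explicitly overridden).

Alternative maps (Kors, inverse Dower) can be supplied as a 3x8
matrix over the same input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import ECGRecord, VCGRecord, VCG_LEADS

__all__ = ["VCGCoefficients", "FRANK_INPUT_LEADS", "ecg_to_vcg", "vcg_loop"]

#: Input lead order of the coefficient matrix columns.
FRANK_INPUT_LEADS: tuple[str, ...] = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

# Rows Vx, Vy, Vz; columns in FRANK_INPUT_LEADS order. The outer
# negation of the Vx and Vz defining expressions is already folded in.
_DEFAULT_MATRIX = np.array([
    # I        II       V1      V2      V3      V4      V5      V6
    [-0.156,  0.010,  0.172,  0.074, -0.122, -0.231, -0.239, -0.194],  # Vx
    [-0.227,  0.887,  0.057, -0.019, -0.106, -0.022,  0.041,  0.048],  # Vy
    [-0.022, -0.102,  0.229,  0.310,  0.246,  0.063, -0.055, -0.108],  # Vz
])


@dataclass(frozen=True)
class VCGCoefficients:
    """3x8 map from (I, II, V1..V6) to (Vx, Vy, Vz), dimensionless."""

    matrix: np.ndarray = field(default_factory=lambda: _DEFAULT_MATRIX.copy())
    allow_unchecked: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 8):
            raise ValueError(f"coefficient matrix must be 3x8, got {m.shape}")
        if not self.allow_unchecked and np.any(np.abs(m) > 10.0):
            bad = np.argwhere(np.abs(m) > 10.0)[0]
            raise ValueError(
                f"coefficient [{'xyz'[bad[0]]}, {FRANK_INPUT_LEADS[bad[1]]}] = "
                f"{m[tuple(bad)]} is outside the plausible sub-unit range of "
                "Frank-synthesis matrices; pass allow_unchecked=True to force")
        object.__setattr__(self, "matrix", m)


def ecg_to_vcg(rec: ECGRecord, coeffs: VCGCoefficients | None = None) -> VCGRecord:
    """Per-sample linear map of the eight independent leads to (Vx, Vy, Vz).

    Leads III/aVR/aVL/aVF are redundant and unused. Raises ``KeyError``
    if a required lead is absent.
    """
    coeffs = coeffs if coeffs is not None else VCGCoefficients()
    stack = np.vstack([rec.lead(name) for name in FRANK_INPUT_LEADS])
    return VCGRecord(
        record_id=rec.record_id,
        signals=coeffs.matrix @ stack,
        lead_names=VCG_LEADS,
        fs=rec.fs,
        labels=rec.labels,
        meta=dict(rec.meta),
    )


def vcg_loop(rec: VCGRecord) -> np.ndarray:
    """The 3-D phase trajectory as an [n_samples, 3] point sequence.

    This is the (Vx, Vy, Vz) loop usually rendered for visual
    inspection; no resampling or smoothing is applied.
    """
    return np.asarray(rec.signals.T, dtype=float).copy()
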