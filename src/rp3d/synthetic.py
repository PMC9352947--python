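"""Class-conditional synthetic 12-lead ECG generator.

Each beat is a sum of Gaussian deflections (P, Q, R, S, T) placed on a
per-lead amplitude template, in the spirit of ECGSYN-style surrogate
generators rather than a biophysical torso model. The four rhythm
classes differ by construction:

* NSR  — regular RR, P waves present, narrow QRS, normal PR;
* AF   — no P waves, a 4-9 Hz low-amplitude fibrillatory baseline,
         RR drawn from a lognormal with a large coefficient of
         variation;
* LBBB — widened, notched QRS (two merged R deflections);
* IAVB — prolonged PR interval (slow atrioventricular conduction),
         otherwise sinus morphology.

Only the eight electrically independent leads (I, II, V1-V6) get their
own templates; the remaining limb leads are derived exactly
(III = II - I, aVR = -(I+II)/2, aVL = I - II/2, aVF = II - I/2), so the
limb-lead identities hold to the last bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional

import numpy as np

from .records import ECGRecord, RhythmClass, STANDARD_12_LEADS

__all__ = ["SynthConfig", "generate_record", "generate_cohort", "class_defaults"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator knobs. ``None`` morphology fields fall back to the
    rhythm class's clinical surrogate value (see :func:`class_defaults`).
    """

    fs: float = 500.0                   # Hz
    duration: float = 10.0              # seconds
    heart_rate_bpm: float = 72.0        # cohort mean
    heart_rate_jitter_bpm: float = 8.0  # sd of the per-record rate draw
    pr_interval: Optional[float] = None     # s, P-onset to QRS-onset
    qrs_width: Optional[float] = None       # s
    p_wave_present: Optional[bool] = None
    rr_irregularity: Optional[float] = None  # CV of the RR series
    noise_sd: float = 0.01              # mV, additive white noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.qrs_width is not None and not self.qrs_width > 0:
            raise ValueError(f"qrs_width must be > 0, got {self.qrs_width}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


# Per-class surrogate morphology: (pr_interval, qrs_width, p_present, rr_cv)
_CLASS_DEFAULTS: dict[RhythmClass, tuple[float, float, bool, float]] = {
    RhythmClass.NSR: (0.16, 0.08, True, 0.03),
    RhythmClass.AF: (0.16, 0.08, False, 0.20),
    RhythmClass.LBBB: (0.16, 0.14, True, 0.03),
    RhythmClass.IAVB: (0.28, 0.08, True, 0.03),
}


def class_defaults(cls: RhythmClass) -> dict:
    """Morphology defaults encoding each class's defining feature."""
    pr, qrs, p, cv = _CLASS_DEFAULTS[cls]
    return {"pr_interval": pr, "qrs_width": qrs,
            "p_wave_present": p, "rr_irregularity": cv}


def _resolve(cls: RhythmClass, cfg: SynthConfig) -> SynthConfig:
    d = class_defaults(cls)
    resolved = replace(
        cfg,
        pr_interval=cfg.pr_interval if cfg.pr_interval is not None else d["pr_interval"],
        qrs_width=cfg.qrs_width if cfg.qrs_width is not None else d["qrs_width"],
        p_wave_present=cfg.p_wave_present if cfg.p_wave_present is not None else d["p_wave_present"],
        rr_irregularity=cfg.rr_irregularity if cfg.rr_irregularity is not None else d["rr_irregularity"],
    )
    # Reject configurations that contradict the class definition.
    if cls is RhythmClass.AF:
        if resolved.p_wave_present:
            raise ValueError("AF records cannot carry P waves")
        if resolved.rr_irregularity < 0.15:
            raise ValueError(f"AF requires rr_irregularity >= 0.15, got {resolved.rr_irregularity}")
    if cls is RhythmClass.LBBB and resolved.qrs_width < 0.12:
        raise ValueError(f"LBBB requires qrs_width >= 0.12 s, got {resolved.qrs_width}")
    if cls is RhythmClass.IAVB and resolved.pr_interval < 0.20:
        raise ValueError(f"IAVB requires pr_interval >= 0.20 s, got {resolved.pr_interval}")
    return resolved


# Per-lead wave amplitudes (mV) for the eight independent leads, rows in
# the order (I, II, V1..V6), columns (P, Q, R, S, T). Values follow the
# usual adult surface-ECG ranges: dominant R in lateral leads, rS
# pattern in V1-V2, upright P and T in I/II/V4-V6.
_TEMPLATE_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")
_AMP = np.array([
    #  P      Q      R      S      T
    [0.15, -0.06, 0.75, -0.12, 0.22],   # I
    [0.22, -0.08, 1.10, -0.15, 0.30],   # II
    [0.06, 0.00, 0.25, -0.90, -0.10],   # V1
    [0.08, 0.00, 0.40, -0.75, 0.12],    # V2
    [0.09, -0.03, 0.70, -0.45, 0.20],   # V3
    [0.11, -0.05, 1.25, -0.25, 0.30],   # V4
    [0.13, -0.06, 1.35, -0.15, 0.28],   # V5
    [0.12, -0.05, 1.05, -0.10, 0.24],   # V6
])


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _beat_waveform(t_rel: np.ndarray, cfg: SynthConfig, notched: bool) -> np.ndarray:
    """Waveforms of one beat for the eight template leads.

    ``t_rel`` is time relative to the R peak (s); returns [8, len(t)].
    """
    qrs = cfg.qrs_width
    out = np.zeros((len(_TEMPLATE_LEADS), t_rel.size))
    # QRS complex: Q and S flank the R peak, widths scale with QRS width.
    q_c, s_c = -0.40 * qrs, 0.40 * qrs
    sigma_r = 0.16 * qrs
    for li in range(len(_TEMPLATE_LEADS)):
        p_a, q_a, r_a, s_a, t_a = _AMP[li]
        if notched:
            # LBBB surrogate: R split into two merged humps (notch).
            out[li] += 0.62 * r_a * _gauss(t_rel, -0.18 * qrs, 1.6 * sigma_r)
            out[li] += 0.62 * r_a * _gauss(t_rel, +0.18 * qrs, 1.6 * sigma_r)
        else:
            out[li] += r_a * _gauss(t_rel, 0.0, sigma_r)
        out[li] += q_a * _gauss(t_rel, q_c, 0.5 * sigma_r * 2.0)
        out[li] += s_a * _gauss(t_rel, s_c, 0.5 * sigma_r * 2.0)
        if cfg.p_wave_present:
            # P center sits one PR interval before QRS onset (plus half
            # the P width so the stated PR is onset-to-onset).
            p_center = -(cfg.pr_interval + 0.5 * qrs)
            out[li] += p_a * _gauss(t_rel, p_center, 0.025)
        out[li] += t_a * _gauss(t_rel, 0.30 + 0.5 * qrs, 0.07)
    return out


def _rr_series(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw RR intervals (s) covering the record duration."""
    rate = cfg.heart_rate_bpm + cfg.heart_rate_jitter_bpm * rng.standard_normal()
    rate = float(np.clip(rate, 40.0, 180.0))
    mean_rr = 60.0 / rate
    cv = cfg.rr_irregularity
    n_max = int(np.ceil(cfg.duration / mean_rr * 2)) + 8
    if cv >= 0.15:
        # AF surrogate: lognormal RR with the requested CV.
        sigma2 = np.log(1.0 + cv**2)
        rr = rng.lognormal(np.log(mean_rr) - sigma2 / 2, np.sqrt(sigma2), n_max)
    else:
        rr = mean_rr * (1.0 + cv * rng.standard_normal(n_max))
    return np.clip(rr, 0.25, 2.5)


def generate_record(cls: RhythmClass, cfg: SynthConfig = SynthConfig(),
                    record_id: str | None = None) -> ECGRecord:
    """Generate one 12-lead record of rhythm class ``cls``.

    Identical (cls, cfg) pairs — including ``cfg.seed`` — produce
    bit-identical records. Annotations used by the generator (RR
    series, PR, QRS width, P flag, R-peak times) land in ``meta``.
    """
    if not isinstance(cls, RhythmClass):
        raise TypeError(f"cls must be a RhythmClass, got {cls!r}")
    cfg = _resolve(cls, cfg)
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.fs * cfg.duration))
    t = np.arange(n) / cfg.fs

    rr = _rr_series(cfg, rng)
    r_times = np.cumsum(rr) - rr[0] + 0.35  # first R peak ~0.35 s in
    r_times = r_times[r_times < cfg.duration + 1.0]
    rr_used = np.diff(r_times)

    sig8 = np.zeros((len(_TEMPLATE_LEADS), n))
    notched = cls is RhythmClass.LBBB
    for r_t in r_times:
        # Only evaluate the beat on a window around the R peak.
        lo = max(0, int((r_t - 0.7) * cfg.fs))
        hi = min(n, int((r_t + 0.7) * cfg.fs) + 1)
        if lo >= hi:
            continue
        sig8[:, lo:hi] += _beat_waveform(t[lo:hi] - r_t, cfg, notched)

    if cls is RhythmClass.AF:
        # Fibrillatory baseline: a few sinusoids in the 4-9 Hz band,
        # coherent across leads with per-lead gains.
        gains = 0.04 + 0.02 * rng.random(len(_TEMPLATE_LEADS))
        base = np.zeros(n)
        for _ in range(4):
            f = rng.uniform(4.0, 9.0)
            phase = rng.uniform(0, 2 * np.pi)
            base += np.sin(2 * np.pi * f * t + phase)
        sig8 += gains[:, None] * base[None, :] / 4.0

    if cfg.noise_sd > 0:
        sig8 += cfg.noise_sd * rng.standard_normal(sig8.shape)

    lead_i, lead_ii = sig8[0], sig8[1]
    full = np.empty((12, n))
    full[0] = lead_i
    full[1] = lead_ii
    full[2] = lead_ii - lead_i             # III
    full[3] = -(lead_i + lead_ii) / 2.0    # aVR
    full[4] = lead_i - lead_ii / 2.0       # aVL
    full[5] = lead_ii - lead_i / 2.0       # aVF
    full[6:12] = sig8[2:8]                 # V1..V6

    rid = record_id if record_id is not None else f"{cls.name}-{cfg.seed:08d}"
    return ECGRecord(
        record_id=rid,
        signals=full,
        lead_names=STANDARD_12_LEADS,
        fs=cfg.fs,
        labels=frozenset({cls}),
        meta={
            "rr_intervals": rr_used,
            "pr_interval": cfg.pr_interval,
            "qrs_width": cfg.qrs_width,
            "p_wave_present": cfg.p_wave_present,
            "rr_irregularity": cfg.rr_irregularity,
            "r_peak_times": r_times,
        },
    )


def generate_cohort(counts: Mapping[RhythmClass, int],
                    cfg: SynthConfig = SynthConfig()) -> list[ECGRecord]:
    """Generate ``counts[cls]`` single-labelled records per class.

    Record ids are ``<CLASS><running index>``; per-record seeds are
    derived from ``cfg.seed`` via a seed sequence, so the whole cohort
    is reproducible from one integer.
    """
    for cls, c in counts.items():
        if c < 0:
            raise ValueError(f"negative count for {cls}: {c}")
    total = sum(counts.values())
    child_seeds = np.random.SeedSequence(cfg.seed).generate_state(max(total, 1)) & 0x7FFFFFFF
    out: list[ECGRecord] = []
    i = 0
    for cls in RhythmClass:          # fixed class order => stable ids
        for k in range(counts.get(cls, 0)):
            rec_cfg = replace(cfg, seed=int(child_seeds[i]))
            out.append(generate_record(cls, rec_cfg, record_id=f"{cls.name}{k:05d}"))
            i += 1
    return out
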