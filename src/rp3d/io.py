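"""Reading, writing, resampling and label-filtering of ECG records.

Two on-disk formats are supported:

* WFDB-compatible record pairs — a text header (``<name>.hea``) plus a
  format-16 signal file (``<name>.dat``, interleaved little-endian
  int16 with per-lead gain/baseline). The reader/writer here covers
  exactly that subset of the WFDB specification.
* Plain CSV — one header row of lead names, one column per lead,
  samples in mV.

Rhythm labels travel in a JSON sidecar ``{record_id: ["AF", ...]}``.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .records import (ECGRecord, RhythmClass, STANDARD_12_LEADS, VCG_LEADS,
                      canonical_lead_name)

__all__ = [
    "write_wfdb", "write_csv", "read_record", "write_labels", "read_labels",
    "resample", "filter_single_label",
]

_DEFAULT_GAIN = 1000.0   # adc units per mV -> 0.001 mV quantization


def write_wfdb(rec: ECGRecord, directory: str | Path, gain: float = _DEFAULT_GAIN) -> Path:
    """Write ``<record_id>.hea`` + ``<record_id>.dat`` (format 16).

    Samples are quantized to ``round(mV * gain)`` and clipped to the
    int16 range; the gain and a zero baseline are recorded per lead so
    reading recovers mV within 0.5/gain.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = rec.record_id
    adc = np.round(rec.signals * gain)
    if np.any(np.abs(adc) > 32767):
        raise ValueError(f"record {name!r} exceeds int16 range at gain {gain}")
    adc = adc.astype("<i2")
    # Interleaved sample-major layout, one shared .dat for all leads.
    adc.T.reshape(-1).tofile(directory / f"{name}.dat")
    lines = [f"{name} {rec.n_leads} {rec.fs:g} {rec.n_samples}"]
    for lead in rec.lead_names:
        lines.append(f"{name}.dat 16 {gain:g}(0)/mV 16 0 0 0 0 {lead}")
    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")
    return directory / f"{name}.hea"


def _read_wfdb(path: Path) -> ECGRecord:
    if path.suffix == ".hea":
        path = path.with_suffix("")
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"no header file {hea}")
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    n_sig, fs, n_samples = int(head[1]), float(head[2]), int(head[3])
    leads, gains, baselines = [], [], []
    for ln in lines[1:1 + n_sig]:
        parts = ln.split()
        fmt = parts[1]
        if fmt != "16":
            raise ValueError(f"unsupported WFDB signal format {fmt!r} (only 16)")
        spec = parts[2]          # gain(baseline)/units
        units = "adu"
        if "/" in spec:
            spec, units = spec.split("/", 1)
        baseline = 0.0
        if "(" in spec:
            spec, b = spec.rstrip(")").split("(")
            baseline = float(b)
        gain = float(spec) if spec else 200.0
        if units == "mV":
            scale = 1.0
        elif units in ("uV", "µV"):
            scale = 1000.0
        else:
            raise ValueError(
                f"ambiguous amplitude units {units!r} in {hea.name}; "
                "expected mV or uV — refusing to guess")
        gains.append(gain * scale)
        baselines.append(baseline)
        leads.append(canonical_lead_name(parts[-1]))
    raw = np.fromfile(path.with_suffix(".dat"), dtype="<i2")
    if raw.size != n_sig * n_samples:
        raise ValueError(f"{path.with_suffix('.dat')} holds {raw.size} samples, "
                         f"header promises {n_sig * n_samples}")
    adc = raw.reshape(n_samples, n_sig).T.astype(float)
    mv = (adc - np.asarray(baselines)[:, None]) / np.asarray(gains)[:, None]
    return ECGRecord(record_id=path.name, signals=mv, lead_names=tuple(leads), fs=fs)


def write_csv(rec: ECGRecord, path: str | Path) -> Path:
    """One column per lead (header = lead names), samples in mV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rec.signals.T, columns=list(rec.lead_names)).to_csv(path, index=False)
    return path


def _read_csv(path: Path, fs: float) -> ECGRecord:
    df = pd.read_csv(path)
    leads = tuple(canonical_lead_name(c) for c in df.columns)
    return ECGRecord(record_id=path.stem, signals=df.to_numpy().T,
                     lead_names=leads, fs=fs)


def _check_leads(rec: ECGRecord, expect: str) -> None:
    if expect == "any":
        return
    want = STANDARD_12_LEADS if expect == "ecg12" else VCG_LEADS
    if expect == "auto":
        want = VCG_LEADS if set(rec.lead_names) <= set(VCG_LEADS) else STANDARD_12_LEADS
    missing = [l for l in want if l not in rec.lead_names]
    if missing:
        raise ValueError(f"record {rec.record_id!r} is missing lead(s) "
                         f"{missing} (has {list(rec.lead_names)})")


def read_record(path: str | Path, format: str = "wfdb", *, fs: float | None = None,
                labels: frozenset[RhythmClass] | None = None,
                expect: str = "auto") -> ECGRecord:
    """Read one record; ``expect`` ∈ {auto, ecg12, vcg3, any} controls
    the lead-completeness check. CSV carries no sampling rate, so
    ``fs`` is required for CSV input.
    """
    path = Path(path)
    if format == "wfdb":
        rec = _read_wfdb(path)
    elif format == "csv":
        if fs is None:
            raise ValueError("CSV input carries no sampling rate; pass fs=")
        rec = _read_csv(path, fs)
    else:
        raise ValueError(f"unknown format {format!r}")
    _check_leads(rec, expect)
    if labels is not None:
        rec.labels = frozenset(labels)
    return rec


def write_labels(records: list[ECGRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {r.record_id: sorted(c.name for c in r.labels) for r in records}
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_labels(path: str | Path) -> dict[str, frozenset[RhythmClass]]:
    raw = json.loads(Path(path).read_text())
    return {rid: frozenset(RhythmClass.from_name(n) for n in names)
            for rid, names in raw.items()}


def resample(rec: ECGRecord, target_fs: float) -> ECGRecord:
    """Polyphase (anti-aliased) resampling to ``target_fs``.

    The output has ``round(n_samples * target_fs / fs)`` samples;
    labels, id and lead order are preserved.
    """
    if not target_fs > 0:
        raise ValueError(f"target_fs must be > 0, got {target_fs}")
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = sps.resample_poly(rec.signals, frac.numerator, frac.denominator, axis=1)
    n_expect = int(round(rec.n_samples * target_fs / rec.fs))
    if out.shape[1] > n_expect:
        out = out[:, :n_expect]
    elif out.shape[1] < n_expect:
        out = np.pad(out, ((0, 0), (0, n_expect - out.shape[1])), mode="edge")
    return ECGRecord(record_id=rec.record_id, signals=out,
                     lead_names=rec.lead_names, fs=target_fs,
                     labels=rec.labels, meta=dict(rec.meta))


def filter_single_label(records: list[ECGRecord],
                        classes: list[RhythmClass] | None = None) -> list[ECGRecord]:
    """Keep records whose label set is exactly one of ``classes``.

    Multi-labelled and unlabelled records are dropped; input order is
    preserved. ``classes`` defaults to all four rhythm classes.
    """
    allowed = set(classes) if classes is not None else set(RhythmClass)
    return [r for r in records
            if len(r.labels) == 1 and next(iter(r.labels)) in allowed]
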