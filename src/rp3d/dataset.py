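"""Cohort splitting, windowing and 3-D recurrence-volume assembly.

The pipeline mirrors the inter-patient evaluation design used for the
PTB-XL-style cohorts:

1. drop multi-labelled records (``rp3d.io.filter_single_label``);
2. optionally subsample over-represented classes (seeded, uniform);
3. draw a *record-level* test set of floor(n/5) per class, so no
   subject contributes to both training and test;
4. window the remaining records into 5-s (1000-sample @200 Hz)
   segments with class-specific overlapping starts that re-balance
   the classes: NSR/AF one window, I-AVB two, LBBB three;
5. split the train+validation *segments* 80/20 (floor on the train
   side), and optionally regroup them into record-grouped CV folds.

Window starts are 0-based half-open [start, start+1000); the test
split precedes augmentation (record level) while train/val is split
at segment level — the combination that makes the per-class counts
work out to an exact 80/20 grid with floors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .records import ECGRecord, RhythmClass, STANDARD_12_LEADS, VCG_LEADS
from .recurrence import EmbeddingParams, rp_from_segment
from .vcg import VCGCoefficients, ecg_to_vcg

__all__ = [
    "WindowRule", "DEFAULT_WINDOW_RULES", "Segment", "SplitPlan", "RPConfig",
    "RPVolume", "subsample_records", "segment_records", "make_split",
    "make_cv_folds", "build_volume", "build_volumes", "save_volumes",
    "load_volumes",
]


@dataclass(frozen=True)
class WindowRule:
    """Per-class window starts (samples) and length (1000 @ 200 Hz)."""

    rhythm: RhythmClass
    window_starts: tuple[int, ...]
    window_length: int = 1000


#: The class-specific augmentation grid: one 5-s window for the two
#: abundant classes, two for I-AVB, three (overlapping) for LBBB.
DEFAULT_WINDOW_RULES: dict[RhythmClass, WindowRule] = {
    RhythmClass.NSR: WindowRule(RhythmClass.NSR, (0,)),
    RhythmClass.AF: WindowRule(RhythmClass.AF, (0,)),
    RhythmClass.LBBB: WindowRule(RhythmClass.LBBB, (0, 500, 1000)),
    RhythmClass.IAVB: WindowRule(RhythmClass.IAVB, (0, 1000)),
}


class Segment(NamedTuple):
    """One classifier sample: a window of one record."""

    record_id: str
    window_start: int
    label: RhythmClass


def _single_label(rec) -> RhythmClass:
    labels = rec.labels
    if len(labels) != 1:
        raise ValueError(f"record {rec.record_id!r} is not single-labelled: "
                         f"{sorted(c.name for c in labels)}")
    return next(iter(labels))


def subsample_records(records: Sequence, limits: Mapping[RhythmClass, int],
                      seed: int) -> list:
    """Uniformly subsample classes listed in ``limits`` (without
    replacement, seeded); other classes pass through. Order preserved.
    """
    rng = np.random.default_rng(seed)
    keep: set[int] = set()
    by_class: dict[RhythmClass, list[int]] = {}
    for i, rec in enumerate(records):
        by_class.setdefault(_single_label(rec), []).append(i)
    for cls, idxs in by_class.items():
        if cls in limits and len(idxs) > limits[cls]:
            chosen = rng.choice(len(idxs), size=limits[cls], replace=False)
            keep.update(idxs[j] for j in chosen)
        else:
            keep.update(idxs)
    return [records[i] for i in range(len(records)) if i in keep]


def segment_records(records: Sequence,
                    rules: Mapping[RhythmClass, WindowRule] = DEFAULT_WINDOW_RULES
                    ) -> list[Segment]:
    """Expand records into (record_id, window_start, label) segments.

    Deterministic order: input record order, then start offset. A
    record too short for its class's last window raises.
    """
    out: list[Segment] = []
    for rec in records:
        cls = _single_label(rec)
        rule = rules[cls]
        needed = rule.window_starts[-1] + rule.window_length
        if rec.n_samples < needed:
            raise ValueError(
                f"record {rec.record_id!r} has {rec.n_samples} samples but "
                f"class {cls.name} windows need {needed}")
        for start in rule.window_starts:
            out.append(Segment(rec.record_id, start, cls))
    return out


@dataclass
class SplitPlan:
    """Record→{trainval,test} and segment→{train,val,test} assignment."""

    seed: int
    test_record_ids: frozenset[str]
    trainval_record_ids: frozenset[str]
    train: list[Segment]
    val: list[Segment]
    test: list[Segment]

    def counts(self) -> dict[str, dict[str, int]]:
        """Per-class segment counts per split (class name keyed)."""
        out: dict[str, dict[str, int]] = {}
        for name, segs in (("train", self.train), ("val", self.val), ("test", self.test)):
            for s in segs:
                out.setdefault(s.label.name, {}).setdefault(name, 0)
                out[s.label.name][name] += 1
        return out

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "seed": self.seed,
            "test_record_ids": sorted(self.test_record_ids),
            "trainval_record_ids": sorted(self.trainval_record_ids),
            **{k: [[s.record_id, s.window_start, s.label.name] for s in v]
               for k, v in (("train", self.train), ("val", self.val), ("test", self.test))},
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        raw = json.loads(Path(path).read_text())
        def segs(key):
            return [Segment(r, int(w), RhythmClass.from_name(l)) for r, w, l in raw[key]]
        return cls(seed=raw["seed"],
                   test_record_ids=frozenset(raw["test_record_ids"]),
                   trainval_record_ids=frozenset(raw["trainval_record_ids"]),
                   train=segs("train"), val=segs("val"), test=segs("test"))


def make_split(records: Sequence, seed: int,
               rules: Mapping[RhythmClass, WindowRule] = DEFAULT_WINDOW_RULES,
               train_fraction: float = 0.8) -> SplitPlan:
    """Inter-patient split reproducing the 80/20 count grid.

    Per class: floor(n/5) records are drawn uniformly (seeded) as the
    test set and windowed; the remaining records are windowed and
    their segments shuffled into floor(0.8*n) train + remainder val.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[RhythmClass, list] = {}
    for rec in records:
        by_class.setdefault(_single_label(rec), []).append(rec)

    test_ids: set[str] = set()
    trainval_ids: set[str] = set()
    train: list[Segment] = []
    val: list[Segment] = []
    test: list[Segment] = []
    for cls in RhythmClass:          # fixed order for determinism
        recs = by_class.get(cls)
        if not recs:
            continue
        n = len(recs)
        if n < 5:
            raise ValueError(f"class {cls.name} has only {n} records; "
                             "need at least 5 for a 1-in-5 test draw")
        n_test = n // 5
        order = rng.permutation(n)
        test_recs = [recs[i] for i in order[:n_test]]
        tv_recs = [recs[i] for i in sorted(order[n_test:])]
        test_ids.update(r.record_id for r in test_recs)
        trainval_ids.update(r.record_id for r in tv_recs)
        test.extend(segment_records(test_recs, rules))
        tv_segments = segment_records(tv_recs, rules)
        seg_order = rng.permutation(len(tv_segments))
        n_train = int(np.floor(train_fraction * len(tv_segments)))
        train.extend(tv_segments[i] for i in sorted(seg_order[:n_train]))
        val.extend(tv_segments[i] for i in sorted(seg_order[n_train:]))
    return SplitPlan(seed=seed, test_record_ids=frozenset(test_ids),
                     trainval_record_ids=frozenset(trainval_ids),
                     train=train, val=val, test=test)


def make_cv_folds(segments: Sequence[Segment], k: int = 5, seed: int = 0
                  ) -> list[tuple[list[Segment], list[Segment]]]:
    """k record-grouped (train, val) folds over train+val segments.

    Validation folds are disjoint and cover every segment; all
    segments of one record share a fold, preserving the inter-patient
    property inside cross-validation. Assignment is stratified by
    class: per class, records are shuffled (seeded) and dealt
    greedily to the currently smallest fold, so folds are
    class-balanced and sizes differ by at most the largest per-record
    segment count (exactly balanced when every record has one
    segment).
    """
    if k < 2:
        raise ValueError(f"need k >= 2 folds, got {k}")
    rng = np.random.default_rng(seed)
    by_record: dict[str, list[Segment]] = {}
    for s in segments:
        by_record.setdefault(s.record_id, []).append(s)
    by_class: dict[RhythmClass, list[str]] = {}
    for rid in sorted(by_record):
        by_class.setdefault(by_record[rid][0].label, []).append(rid)
    fold_sizes = [0] * k
    fold_members: list[list[str]] = [[] for _ in range(k)]
    for cls in sorted(by_class, key=lambda c: c.index):
        rec_ids = by_class[cls]
        rng.shuffle(rec_ids)
        for rid in rec_ids:
            j = int(np.argmin(fold_sizes))
            fold_members[j].append(rid)
            fold_sizes[j] += len(by_record[rid])
    folds = []
    for j in range(k):
        val_ids = set(fold_members[j])
        val = [s for s in segments if s.record_id in val_ids]
        tr = [s for s in segments if s.record_id not in val_ids]
        folds.append((tr, val))
    return folds


@dataclass(frozen=True)
class RPConfig:
    """How each lead segment becomes a recurrence image."""

    embedding: EmbeddingParams = EmbeddingParams()
    normalization: str = "zscore"        # none | minmax | zscore
    side: int = 128                      # classifier resolution
    decimate: int = 1                    # optional pre-RP decimation


@dataclass
class RPVolume:
    """Lead-stacked recurrence volume: the classifier input sample."""

    values: np.ndarray                   # [C, H, W] float32
    channel_names: tuple[str, ...]
    label: RhythmClass | None
    provenance: tuple[str, int]          # (record_id, window_start)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float32)
        if v.ndim != 3:
            raise ValueError(f"volume must be [C, H, W], got {v.shape}")
        if v.shape[0] != len(self.channel_names):
            raise ValueError(f"{v.shape[0]} channels but "
                             f"{len(self.channel_names)} channel names")
        self.values = v


def build_volume(rec: ECGRecord, window_start: int, mode: str = "ecg12",
                 rp: RPConfig = RPConfig(),
                 coeffs: VCGCoefficients | None = None,
                 window_length: int = 1000) -> RPVolume:
    """One window of one record -> normalized, resized, lead-stacked
    recurrence volume (12 channels in ecg12 mode, 3 in vcg3 mode; the
    channel order is the canonical lead order).
    """
    if mode == "ecg12":
        channels = STANDARD_12_LEADS
        source = rec
    elif mode == "vcg3":
        channels = VCG_LEADS
        source = rec if rec.lead_names == VCG_LEADS else ecg_to_vcg(rec, coeffs)
    else:
        raise ValueError(f"unknown mode {mode!r} (expected ecg12 or vcg3)")
    stop = window_start + window_length
    if stop > source.n_samples:
        raise ValueError(f"window [{window_start}, {stop}) exceeds record "
                         f"{rec.record_id!r} length {source.n_samples}")
    planes = []
    for name in channels:
        seg = source.lead(name)[window_start:stop]
        planes.append(rp_from_segment(seg, rp.embedding, rp.normalization,
                                      rp.side, rp.decimate).values)
    label = next(iter(rec.labels)) if len(rec.labels) == 1 else None
    return RPVolume(values=np.stack(planes).astype(np.float32),
                    channel_names=channels, label=label,
                    provenance=(rec.record_id, window_start))


def build_volumes(records: Iterable[ECGRecord], segments: Sequence[Segment],
                  mode: str = "ecg12", rp: RPConfig = RPConfig(),
                  coeffs: VCGCoefficients | None = None) -> list[RPVolume]:
    """Build volumes for every segment; records are indexed by id.

    In vcg3 mode each record is converted once, not per window.
    """
    by_id: dict[str, ECGRecord] = {}
    for rec in records:
        by_id[rec.record_id] = rec
    cache: dict[str, ECGRecord] = {}
    out = []
    for seg in segments:
        if seg.record_id not in by_id:
            raise KeyError(f"segment references unknown record {seg.record_id!r}")
        rec = by_id[seg.record_id]
        if mode == "vcg3" and rec.lead_names != VCG_LEADS:
            if seg.record_id not in cache:
                cache[seg.record_id] = ecg_to_vcg(rec, coeffs)
            rec = cache[seg.record_id]
        out.append(build_volume(rec, seg.window_start, mode, rp, coeffs))
    return out


def save_volumes(volumes: Sequence[RPVolume], path: str | Path) -> Path:
    """HDF5 layout: "volumes" float32 [n, C, H, W], "labels" int8
    (class index, -1 if unknown), "provenance" strings."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.stack([v.values for v in volumes])
    labels = np.array([v.label.index if v.label is not None else -1
                       for v in volumes], dtype=np.int8)
    prov = np.array([f"{v.provenance[0]}:{v.provenance[1]}" for v in volumes],
                    dtype=h5py.string_dtype())
    with h5py.File(path, "w") as f:
        f.create_dataset("volumes", data=arr)
        f.create_dataset("labels", data=labels)
        f.create_dataset("provenance", data=prov)
        f.attrs["channel_names"] = list(volumes[0].channel_names)
    return path


def load_volumes(path: str | Path) -> list[RPVolume]:
    import h5py

    with h5py.File(path, "r") as f:
        arr = f["volumes"][...]
        labels = f["labels"][...]
        prov = [p.decode() if isinstance(p, bytes) else p for p in f["provenance"][...]]
        channels = tuple(f.attrs["channel_names"])
    out = []
    for i in range(arr.shape[0]):
        rid, _, start = prov[i].rpartition(":")
        label = RhythmClass(int(labels[i])) if labels[i] >= 0 else None
        out.append(RPVolume(values=arr[i], channel_names=channels,
                            label=label, provenance=(rid, int(start))))
    return out
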