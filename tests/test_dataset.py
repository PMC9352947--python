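"""Splitting arithmetic, inter-patient invariants, volume assembly."""

import numpy as np
import pytest

from rp3d.dataset import (DEFAULT_WINDOW_RULES, RPConfig, Segment, SplitPlan,
                          build_volume, build_volumes, load_volumes,
                          make_cv_folds, make_split, save_volumes,
                          segment_records, subsample_records)
from rp3d.records import ECGRecord, RhythmClass, STANDARD_12_LEADS
from rp3d.vcg import ecg_to_vcg

# The published per-class count grid for single-label cohorts of
# (1200, 1200, 370, 689) records: segments, train, val, test.
COUNT_GRID = {
    "NSR": dict(segments=1200, train=768, val=192, test=240),
    "AF": dict(segments=1200, train=768, val=192, test=240),
    "LBBB": dict(segments=1110, train=710, val=178, test=222),
    "IAVB": dict(segments=1378, train=883, val=221, test=274),
}
SINGLE_LABEL_COUNTS = {RhythmClass.NSR: 1200, RhythmClass.AF: 1200,
                       RhythmClass.LBBB: 370, RhythmClass.IAVB: 689}


def test_window_rules():
    assert DEFAULT_WINDOW_RULES[RhythmClass.NSR].window_starts == (0,)
    assert DEFAULT_WINDOW_RULES[RhythmClass.AF].window_starts == (0,)
    assert DEFAULT_WINDOW_RULES[RhythmClass.IAVB].window_starts == (0, 1000)
    assert DEFAULT_WINDOW_RULES[RhythmClass.LBBB].window_starts == (0, 500, 1000)
    assert all(r.window_length == 1000 for r in DEFAULT_WINDOW_RULES.values())


def test_segment_counts_per_class(fake_cohort_factory):
    lbbb = fake_cohort_factory({RhythmClass.LBBB: 370})
    assert len(segment_records(lbbb)) == 1110
    iavb = fake_cohort_factory({RhythmClass.IAVB: 689})
    assert len(segment_records(iavb)) == 1378
    one = fake_cohort_factory({RhythmClass.NSR: 1})
    segs = segment_records(one)
    assert segs == [Segment(one[0].record_id, 0, RhythmClass.NSR)]


def test_segment_order_is_deterministic(fake_cohort_factory):
    recs = fake_cohort_factory({RhythmClass.LBBB: 2})
    segs = segment_records(recs)
    assert [s.window_start for s in segs] == [0, 500, 1000, 0, 500, 1000]


def test_short_record_rejected(fake_cohort_factory):
    recs = fake_cohort_factory({RhythmClass.LBBB: 1}, n_samples=1500)
    with pytest.raises(ValueError, match="windows need"):
        segment_records(recs)


def test_subsample_is_uniform_and_seeded(fake_cohort_factory):
    recs = fake_cohort_factory({RhythmClass.NSR: 500, RhythmClass.LBBB: 50})
    out = subsample_records(recs, {RhythmClass.NSR: 120}, seed=3)
    n_nsr = sum(1 for r in out if RhythmClass.NSR in r.labels)
    assert n_nsr == 120
    assert sum(1 for r in out if RhythmClass.LBBB in r.labels) == 50
    out2 = subsample_records(recs, {RhythmClass.NSR: 120}, seed=3)
    assert [r.record_id for r in out] == [r.record_id for r in out2]


def test_split_reproduces_published_count_grid(fake_cohort_factory):
    """Feeding the four single-label class counts through subsample ->
    split -> segment reproduces the full 80/20 grid, all 12 cells."""
    cohort = fake_cohort_factory(SINGLE_LABEL_COUNTS)
    plan = make_split(cohort, seed=0)
    counts = plan.counts()
    for cls, expect in COUNT_GRID.items():
        assert counts[cls]["train"] == expect["train"]
        assert counts[cls]["val"] == expect["val"]
        assert counts[cls]["test"] == expect["test"]
        total = sum(counts[cls].values())
        assert total == expect["segments"]


def test_split_counts_invariant_to_seed(fake_cohort_factory):
    cohort = fake_cohort_factory(SINGLE_LABEL_COUNTS)
    for seed in (1, 17):
        counts = make_split(cohort, seed=seed).counts()
        for cls, expect in COUNT_GRID.items():
            assert counts[cls]["test"] == expect["test"]
            assert counts[cls]["train"] == expect["train"]


def test_inter_patient_property(fake_cohort_factory):
    cohort = fake_cohort_factory({RhythmClass.LBBB: 37, RhythmClass.NSR: 25})
    plan = make_split(cohort, seed=2)
    assert not plan.test_record_ids & plan.trainval_record_ids
    test_recs = {s.record_id for s in plan.test}
    trainval_recs = {s.record_id for s in plan.train} | {s.record_id for s in plan.val}
    assert not test_recs & trainval_recs


def test_split_conservation(fake_cohort_factory):
    cohort = fake_cohort_factory({c: 20 for c in RhythmClass})
    plan = make_split(cohort, seed=4)
    n_total = len(segment_records(cohort))
    assert len(plan.train) + len(plan.val) + len(plan.test) == n_total


def test_split_determinism_and_serialization(fake_cohort_factory, tmp_path):
    cohort = fake_cohort_factory({c: 10 for c in RhythmClass})
    a = make_split(cohort, seed=9)
    b = make_split(cohort, seed=9)
    assert a.train == b.train and a.val == b.val and a.test == b.test
    path = a.to_json(tmp_path / "plan.json")
    back = SplitPlan.from_json(path)
    assert back.train == a.train and back.test == a.test
    assert back.test_record_ids == a.test_record_ids


def test_split_requires_five_records_per_class(fake_cohort_factory):
    cohort = fake_cohort_factory({RhythmClass.NSR: 4})
    with pytest.raises(ValueError, match="at least 5"):
        make_split(cohort, seed=0)


class TestCVFolds:
    def test_single_segment_records_balance(self, fake_cohort_factory):
        recs = fake_cohort_factory({RhythmClass.NSR: 10})
        segs = segment_records(recs)
        folds = make_cv_folds(segs, k=5, seed=0)
        assert len(folds) == 5
        assert all(len(val) == 2 for _, val in folds)

    def test_folds_partition_and_group_by_record(self, fake_cohort_factory):
        recs = fake_cohort_factory({RhythmClass.LBBB: 11, RhythmClass.IAVB: 7})
        segs = segment_records(recs)
        folds = make_cv_folds(segs, k=5, seed=1)
        all_val = [s for _, val in folds for s in val]
        assert sorted(all_val) == sorted(segs)          # disjoint cover
        for train, val in folds:
            assert not {s.record_id for s in train} & {s.record_id for s in val}

    def test_stratified_coverage(self, fake_cohort_factory):
        recs = fake_cohort_factory({c: 5 for c in RhythmClass})
        folds = make_cv_folds(segment_records(recs), k=5, seed=2)
        for _, val in folds:
            assert {s.label for s in val} == set(RhythmClass)

    def test_determinism(self, fake_cohort_factory):
        recs = fake_cohort_factory({c: 6 for c in RhythmClass})
        segs = segment_records(recs)
        assert make_cv_folds(segs, 5, seed=3) == make_cv_folds(segs, 5, seed=3)

    def test_k_validation(self, fake_cohort_factory):
        segs = segment_records(fake_cohort_factory({RhythmClass.NSR: 5}))
        with pytest.raises(ValueError):
            make_cv_folds(segs, k=1)


class TestVolumes:
    rp16 = RPConfig(side=16)

    def test_ecg12_shape_and_order(self, cohort200):
        rec = cohort200[0]
        vol = build_volume(rec, 0, "ecg12", self.rp16)
        assert vol.values.shape == (12, 16, 16)
        assert vol.channel_names == STANDARD_12_LEADS
        assert vol.provenance == (rec.record_id, 0)

    def test_vcg3_shape(self, cohort200):
        vol = build_volume(cohort200[0], 0, "vcg3", self.rp16)
        assert vol.values.shape == (3, 16, 16)
        assert vol.channel_names == ("Vx", "Vy", "Vz")

    def test_vcg_record_passes_through(self, cohort200):
        vrec = ecg_to_vcg(cohort200[0])
        vol = build_volume(vrec, 0, "vcg3", self.rp16)
        direct = build_volume(cohort200[0], 0, "vcg3", self.rp16)
        np.testing.assert_allclose(vol.values, direct.values, atol=1e-6)

    def test_constant_record_gives_zero_volumes(self):
        rec = ECGRecord("flat", np.ones((12, 2000)), STANDARD_12_LEADS, 200.0,
                        labels={RhythmClass.NSR})
        v1 = build_volume(rec, 0, "ecg12", self.rp16)
        v2 = build_volume(rec, 1000, "ecg12", self.rp16)
        assert np.all(v1.values == 0) and np.all(v2.values == 0)

    def test_window_overrun_rejected(self, cohort200):
        with pytest.raises(ValueError, match="exceeds"):
            build_volume(cohort200[0], 1500, "ecg12", self.rp16)

    def test_channel_slices_are_normalized_rps(self, cohort200):
        vol = build_volume(cohort200[0], 0, "vcg3", RPConfig(side=None, normalization="zscore"))
        for ch in vol.values:
            assert ch.shape == (1000, 1000)
            assert abs(float(ch.mean())) < 1e-3         # z-scored
            np.testing.assert_allclose(ch, ch.T, atol=1e-5)

    def test_build_and_io_round_trip(self, cohort200, tmp_path):
        segs = segment_records(cohort200[:4])
        vols = build_volumes(cohort200, segs, "vcg3", self.rp16)
        assert len(vols) == len(segs)
        path = save_volumes(vols, tmp_path / "v.h5")
        back = load_volumes(path)
        assert len(back) == len(vols)
        np.testing.assert_array_equal(back[0].values, vols[0].values)
        assert back[0].label == vols[0].label
        assert back[0].provenance == vols[0].provenance
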