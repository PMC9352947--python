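import numpy as np
import pytest

from rp3d.records import RhythmClass
from rp3d.synthetic import SynthConfig, generate_cohort, generate_record


@pytest.fixture(scope="session")
def small_cohort():
    """Six records per class, 10 s @ 500 Hz, fixed seed."""
    return generate_cohort({c: 6 for c in RhythmClass}, SynthConfig(seed=42))


@pytest.fixture(scope="session")
def cohort200(small_cohort):
    from rp3d.io import resample

    return [resample(r, 200.0) for r in small_cohort]


@pytest.fixture(scope="session")
def nsr_record():
    return generate_record(RhythmClass.NSR, SynthConfig(seed=7))


class FakeRecord:
    """Lightweight stand-in carrying only the attributes the splitting
    logic reads (id, labels, sample count); synthetic metadata object,
    no signal payload."""

    def __init__(self, record_id: str, cls: RhythmClass, n_samples: int = 2000):
        self.record_id = record_id
        self.labels = frozenset({cls})
        self.n_samples = n_samples


@pytest.fixture
def fake_cohort_factory():
    def make(counts: dict[RhythmClass, int], n_samples: int = 2000):
        recs = []
        for cls, n in counts.items():
            recs.extend(FakeRecord(f"{cls.name}{i:05d}", cls, n_samples)
                        for i in range(n))
        return recs

    return make
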