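import numpy as np
import pytest

from aaakit.profiles import BoundaryAnnotation, Cohort, SliceProfile


def make_profile(counts, pid="P0001"):
    return SliceProfile(patient_id=pid, counts=tuple(int(c) for c in counts))


def make_annotation(pid="P0001", start=None, end=None):
    if start is None:
        return BoundaryAnnotation(patient_id=pid, present=False)
    return BoundaryAnnotation(patient_id=pid, present=True, start=start, end=end)


@pytest.fixture
def small_cohort():
    """Three hand-built patients: two aneurysmal, one normal."""
    profiles = {
        "A": make_profile([100] * 10 + [200] * 10 + [100] * 10, "A"),
        "B": make_profile([150] * 30, "B"),
        "C": make_profile([80] * 12 + [240] * 6 + [80] * 12, "C"),
    }
    annotations = {
        "A": make_annotation("A", 10, 19),
        "B": make_annotation("B"),
        "C": make_annotation("C", 12, 17),
    }
    return Cohort(profiles=profiles, annotations=annotations)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
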