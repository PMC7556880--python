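import numpy as np
import pytest

from comotif.intervals_io import ChromTable, Interval, PeakSet, SequenceStore
from comotif.motifs import bundled_pwm_path, read_pwm


@pytest.fixture(scope="session")
def pwm():
    return read_pwm(bundled_pwm_path())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_chroms():
    return ChromTable([("chr1", 10_000), ("chr2", 5_000)])


@pytest.fixture
def toy_store():
    return SequenceStore({"chr1": "ACGTACGT"})


def make_peaks(label, triples, chroms=None):
    return PeakSet(
        label,
        [Interval(c, s, e, name=f"{label}{i}") for i, (c, s, e) in enumerate(triples)],
        chroms,
    )


@pytest.fixture
def make_peakset():
    return make_peaks
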