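import numpy as np
import pytest

import beatvote as bv
from beatvote.dataset import AamiClass


@pytest.fixture(scope="session")
def easy_record():
    """One low-noise N/V record (seeded, session-cached)."""
    cfg = bv.easy_two_class_config(seed=7, record_duration_s=60.0)
    return bv.generate_record(cfg, "easy-0")


@pytest.fixture(scope="session")
def timing_record():
    """One N/S record where S is marked by premature timing."""
    cfg = bv.timing_discrimination_config(seed=11, record_duration_s=60.0)
    return bv.generate_record(cfg, "timing-0")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def reference_confusion():
    from beatvote.metrics import load_reference_confusion

    return load_reference_confusion()


def make_record(signal, beats, record_id="rec", fs=360.0):
    """Convenience constructor used across test modules."""
    return bv.AnnotatedRecord(
        record_id=record_id,
        signal=np.asarray(signal, dtype=float),
        sampling_rate=fs,
        beats=tuple((int(r), lab) for r, lab in beats),
    )


@pytest.fixture()
def tiny_record():
    """1000-sample flat record with three labelled beats."""
    sig = np.zeros(1000)
    sig[250] = 1.0
    sig[500] = 1.0
    sig[750] = 1.0
    return make_record(
        sig,
        [(250, AamiClass.N), (500, AamiClass.V), (750, AamiClass.N)],
    )
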