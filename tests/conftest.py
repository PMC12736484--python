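import numpy as np
import pytest

from ecgseize import io
from ecgseize.synthetic import inject_seizure, make_recording


@pytest.fixture(scope="session")
def responder_recording():
    """360 s recording with one 45 s seizure raising HR by 70 BPM."""
    rec = make_recording(duration=360.0, seed=7)
    rec, ann = inject_seizure(rec, onset=160.0, duration=45.0, hr_delta=70.0)
    return rec, ann


@pytest.fixture(scope="session")
def preprocessed_responder(responder_recording):
    rec, ann = responder_recording
    series = io.preprocess(rec.signal, rec.sampling_rate)
    return series.samples, ann


@pytest.fixture(scope="session")
def baseline_series():
    """Seizure-free preprocessed 8 Hz series (training material)."""
    rec = make_recording(duration=360.0, seed=11)
    return io.preprocess(rec.signal, rec.sampling_rate).samples


@pytest.fixture
def rng():
    return np.random.default_rng(0)
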