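import numpy as np
import pytest
from hypothesis import settings

from eegcpm.core import BandDefinition, Recording

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

ALPHA = BandDefinition("alpha", 8.0, 13.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noise_recording(rng):
    """4-channel white-noise recording, 20 s at 250 Hz."""
    return Recording(
        subject_id="noise",
        channel_labels=["c0", "c1", "c2", "c3"],
        rate=250.0,
        samples=rng.standard_normal((4, 5000)),
    )


def make_recording(samples, rate=250.0, subject_id="t"):
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    labels = [f"c{i}" for i in range(samples.shape[0])]
    return Recording(subject_id=subject_id, channel_labels=labels, rate=rate, samples=samples)
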