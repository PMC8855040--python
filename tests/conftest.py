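import numpy as np
import pytest

from eegcomplex.io import Recording
from eegcomplex.synth import SynthSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced two-group cohort shared by the integration-style tests."""
    return generate_cohort(SynthSpec(n_young=4, n_old=4, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_recording(samples, fs=200.0, group=None, subject_id="s0"):
    samples = np.atleast_2d(samples)
    labels = tuple(f"ch{i}" for i in range(samples.shape[0]))
    return Recording(
        samples=samples, sampling_rate=fs, channel_labels=labels,
        group=group, subject_id=subject_id,
    )
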