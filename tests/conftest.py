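import numpy as np
import pytest

from bulbarvoice.recording import VoiceRecording
from bulbarvoice.synth import CohortSpec, generate_cohort


def make_tone(freq_hz: float, duration_s: float = 3.0, fs: float = 44100.0,
              amplitude: float = 0.8, **meta) -> VoiceRecording:
    t = np.arange(int(round(duration_s * fs))) / fs
    return VoiceRecording(samples=amplitude * np.sin(2 * np.pi * freq_hz * t),
                          sample_rate_hz=fs, **meta)


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-subject audio cohort (2 per group), shared across tests."""
    spec = CohortSpec(n_control=2, n_bulbar=2, n_nonbulbar=2, seed=7)
    recordings, subjects = generate_cohort(spec)
    return spec, recordings, subjects
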