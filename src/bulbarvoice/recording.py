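"""Voice recording container and RIFF WAV I/O.

A :class:`VoiceRecording` is the raw unit of analysis: one sustained-vowel
phonation together with the subject metadata the downstream stages need
(sex selects pitch-tracker defaults, age feeds the aging correction, group
is the diagnostic label).  Synthetic recordings additionally carry the
ground-truth per-cycle periods/amplitudes they were built from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

VOWELS = ("a", "e", "i", "o", "u")
SEXES = ("male", "female")
GROUPS = ("C", "B", "NB")


@dataclass
class VoiceRecording:
    """One sustained-vowel phonation plus subject metadata.

    Samples are dimensionless amplitudes nominally in [-1, 1]; every
    feature downstream is invariant to a positive rescaling.
    """

    samples: np.ndarray
    sample_rate_hz: float
    subject_id: str = ""
    vowel: str = "a"
    sex: str = "male"
    age_years: float = math.nan
    group: str = "C"
    # Ground truth retained by the synthesizer (None for real recordings).
    true_periods_s: np.ndarray | None = field(default=None, repr=False)
    true_amplitudes: np.ndarray | None = field(default=None, repr=False)
    true_hnr_db: float | None = None
    true_f0_hz: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array (mono)")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.vowel not in VOWELS:
            raise ValueError(f"vowel must be one of {VOWELS}, got {self.vowel!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def with_samples(self, samples: np.ndarray, keep_truth: bool = False) -> "VoiceRecording":
        """Copy of this recording with new samples (ground truth dropped
        unless the caller asserts the cycle table still applies)."""
        out = replace(self, samples=np.asarray(samples, dtype=float))
        if not keep_truth:
            out.true_periods_s = None
            out.true_amplitudes = None
        return out


def read_wav(path: str | Path, **meta) -> VoiceRecording:
    """Read a mono PCM WAV file, normalizing samples to [-1, 1].

    16-, 24- and 32-bit integer and 32-/64-bit float dialects are accepted.
    Keyword arguments become recording metadata (subject_id, vowel, ...).
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.ndim} channels")
    if data.dtype.kind == "i":
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(float) / scale
    elif data.dtype.kind == "u":  # 8-bit unsigned PCM
        samples = (data.astype(float) - 128.0) / 128.0
    else:
        samples = data.astype(float)
    return VoiceRecording(samples=samples, sample_rate_hz=float(rate), **meta)


def write_wav(path: str | Path, rec: VoiceRecording, bits: int = 32) -> None:
    """Write a mono RIFF WAV (32-bit float by default, or 16-bit PCM)."""
    if bits == 32:
        wavfile.write(str(path), int(round(rec.sample_rate_hz)), rec.samples.astype(np.float32))
    elif bits == 16:
        clipped = np.clip(rec.samples, -1.0, 1.0)
        wavfile.write(
            str(path),
            int(round(rec.sample_rate_hz)),
            np.round(clipped * 32767.0).astype(np.int16),
        )
    else:
        raise ValueError("bits must be 16 or 32")
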