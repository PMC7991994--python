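"""Frame-based harmonics-to-noise ratio (HNR).

Per frame, the corrected normalized autocorrelation is searched for its
second local maximum r(tau) (the first being the trivial one at lag 0);
for a signal with harmonic power E_h and noise power E_n, r(tau) estimates
E_h / (E_h + E_n), so

    HNR = 10 log10( r / (1 - r) )  dB

estimates the harmonic-to-noise power ratio.  Frames whose peak amplitude
stays below the silence threshold (relative to the global maximum) are
skipped, as are frames without an admissible autocorrelation peak; the
reported HNR(mean) and HNR(SD) are the sample mean and n-1 standard
deviation over retained frames.

Defaults follow common practice for sustained vowels: 10 ms time step,
60 Hz pitch floor regardless of sex, silence threshold 0.1, and 4.5
periods of the pitch floor per analysis window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .perturbation import UNDEFINED
from .pitch import (
    _corrected_autocorrelation,
    _window_autocorrelation,
    best_period_candidate,
)
from .recording import VoiceRecording

#: r is clamped below 1 by this epsilon so HNR stays finite (caps ~+120 dB).
R_EPSILON = 1e-12


@dataclass
class HarmonicitySettings:
    time_step_s: float = 0.01
    pitch_floor_hz: float = 60.0
    silence_threshold: float = 0.1
    periods_per_window: float = 4.5

    def __post_init__(self) -> None:
        if min(self.time_step_s, self.pitch_floor_hz,
               self.silence_threshold, self.periods_per_window) <= 0:
            raise ValueError("all harmonicity settings must be positive")


class HarmonicityFrame(NamedTuple):
    time_s: float
    r_tau: float
    hnr_db: float


class HarmonicityResult(NamedTuple):
    mean_db: float
    sd_db: float
    frames: list


def hnr_from_r(r: float) -> float:
    """10 log10(r / (1-r)), with r clamped to [eps, 1-eps]."""
    r = min(max(r, R_EPSILON), 1.0 - R_EPSILON)
    return 10.0 * math.log10(r / (1.0 - r))


def harmonicity(rec: VoiceRecording,
                settings: HarmonicitySettings | None = None) -> HarmonicityResult:
    """HNR(mean), HNR(SD) and the per-frame detail for one phonation."""
    if settings is None:
        settings = HarmonicitySettings()
    fs = rec.sample_rate_hz
    x = rec.samples
    win_len = int(round(settings.periods_per_window / settings.pitch_floor_hz * fs))
    if x.size < win_len:
        raise ValueError("recording shorter than one harmonicity window")
    window = np.hanning(win_len)
    nfft = 1 << int(math.ceil(math.log2(2 * win_len)))
    win_acf = _window_autocorrelation(window, nfft)
    lag_min = max(2, int(math.floor(fs / 1200.0)))
    lag_max = int(math.ceil(fs / settings.pitch_floor_hz)) + 1

    global_peak = float(np.max(np.abs(x)))
    step = max(int(round(settings.time_step_s * fs)), 1)
    frames: list[HarmonicityFrame] = []
    for s0 in range(0, x.size - win_len + 1, step):
        frame = x[s0:s0 + win_len]
        if global_peak == 0 or np.max(np.abs(frame)) < settings.silence_threshold * global_peak:
            continue  # silent frame
        racf = _corrected_autocorrelation(frame, window, win_acf, nfft)
        cand = best_period_candidate(racf, lag_min, lag_max, threshold=0.0)
        if cand is None:
            continue
        _, r = cand
        if r <= 0:
            continue
        frames.append(HarmonicityFrame((s0 + win_len / 2.0) / fs, r, hnr_from_r(r)))

    if not frames:
        return HarmonicityResult(UNDEFINED, UNDEFINED, frames)
    values = np.array([f.hnr_db for f in frames])
    sd = float(np.std(values, ddof=1)) if values.size > 1 else UNDEFINED
    return HarmonicityResult(float(np.mean(values)), sd, frames)
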