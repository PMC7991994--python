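"""Autocorrelation pitch tracking for sustained vowels.

Per frame, the local-mean-removed, Hann-windowed signal is autocorrelated
via FFT, and the raw autocorrelation is divided by the autocorrelation of
the window itself, which undoes the taper-induced decay so that a perfectly
periodic frame scores r ~= 1 at its period.  The best candidate lag is the
smallest lag among the near-maximal local peaks (this suppresses the
sub-harmonic ambiguity of the autocorrelation: for a pure tone every
multiple of the period scores ~1, and the fundamental is the shortest).
Frames below the silence threshold, without a sufficiently strong peak, or
whose candidate frequency falls outside [pitch floor, pitch ceiling] are
marked unvoiced; pitch statistics are computed over voiced frames only.

Sex-specific defaults: floor/ceiling 60/300 Hz for males and 100/500 Hz
for females, with analysis time steps of 12.5 ms and 7.5 ms respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.fft import irfft, rfft

from .perturbation import UNDEFINED
from .recording import VoiceRecording

#: Minimum corrected-autocorrelation peak height for a frame to count as voiced.
VOICING_THRESHOLD = 0.45
#: Peaks within this margin of the frame's best peak compete as candidates;
#: the shortest lag wins (fundamental rather than sub-harmonic).
_NEAR_TIE_MARGIN = 0.02
#: Window length for pitch analysis, in periods of the pitch floor.
_PITCH_PERIODS_PER_WINDOW = 3.0


@dataclass
class PitchSettings:
    pitch_floor_hz: float
    pitch_ceiling_hz: float
    time_step_s: float
    silence_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.pitch_floor_hz < self.pitch_ceiling_hz:
            raise ValueError("need 0 < pitch floor < pitch ceiling")
        if not self.time_step_s > 0:
            raise ValueError("time_step_s must be positive")
        if not 0 < self.silence_threshold < 1:
            raise ValueError("silence_threshold must be in (0, 1)")

    @classmethod
    def for_sex(cls, sex: str) -> "PitchSettings":
        if sex == "male":
            return cls(60.0, 300.0, 0.0125)
        if sex == "female":
            return cls(100.0, 500.0, 0.0075)
        raise ValueError(f"unknown sex {sex!r}")


@dataclass
class PitchTrack:
    frame_times_s: np.ndarray
    f0_hz: np.ndarray  # NaN marks unvoiced frames
    settings: PitchSettings

    def voiced(self) -> np.ndarray:
        return self.f0_hz[~np.isnan(self.f0_hz)]


class PitchStats(NamedTuple):
    mean_hz: float
    sd_hz: float
    min_hz: float
    max_hz: float


def _window_autocorrelation(window: np.ndarray, nfft: int) -> np.ndarray:
    spec = rfft(window, nfft)
    acf = irfft(spec * np.conj(spec), nfft)[: window.size]
    return acf / acf[0]


def _corrected_autocorrelation(frame: np.ndarray, window: np.ndarray,
                               win_acf: np.ndarray, nfft: int) -> np.ndarray:
    """Normalized autocorrelation of the frame divided by that of the window."""
    x = (frame - frame.mean()) * window
    spec = rfft(x, nfft)
    acf = irfft(spec * np.conj(spec), nfft)[: frame.size]
    if acf[0] <= 0:
        return np.zeros_like(acf)
    # The correction diverges where the window autocorrelation vanishes
    # (lags near the window length); those lags are never searched, so
    # zero them instead of dividing.
    out = np.zeros_like(acf)
    usable = win_acf > 0.1
    out[usable] = (acf[usable] / acf[0]) / win_acf[usable]
    return out


def _parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample peak location and height through the points i-1, i, i+1."""
    if i <= 0 or i >= y.size - 1:
        return float(i), float(y[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0:
        return float(i), float(y[i])
    d = 0.5 * (y[i - 1] - y[i + 1]) / denom
    d = float(np.clip(d, -0.5, 0.5))
    return i + d, float(y[i] - 0.25 * (y[i - 1] - y[i + 1]) * d)


def best_period_candidate(racf: np.ndarray, lag_min: int, lag_max: int,
                          threshold: float = VOICING_THRESHOLD) -> tuple[float, float] | None:
    """Smallest-lag near-maximal local peak of the corrected autocorrelation.

    Searches local maxima in [lag_min, lag_max]; returns (lag, r) with
    parabolic interpolation, or None when no peak reaches ``threshold``.
    """
    lag_max = min(lag_max, racf.size - 2)
    if lag_max <= lag_min + 1:
        return None
    seg = racf[lag_min:lag_max + 1]
    inner = seg[1:-1]
    is_peak = (inner >= seg[:-2]) & (inner > seg[2:]) & (inner >= threshold)
    peaks = np.nonzero(is_peak)[0] + lag_min + 1
    if peaks.size == 0:
        return None
    best = float(racf[peaks].max())
    chosen = int(peaks[racf[peaks] >= best - _NEAR_TIE_MARGIN][0])
    lag, r = _parabolic_refine(racf, chosen)
    return lag, min(r, 1.0 - 1e-12)


def track_pitch(rec: VoiceRecording, settings: PitchSettings | None = None) -> PitchTrack:
    """Frame-based F0 estimation; unvoiced frames carry NaN."""
    if settings is None:
        settings = PitchSettings.for_sex(rec.sex)
    fs = rec.sample_rate_hz
    x = rec.samples
    win_len = int(round(_PITCH_PERIODS_PER_WINDOW / settings.pitch_floor_hz * fs))
    if x.size < win_len:
        raise ValueError("recording shorter than one pitch analysis window")
    window = np.hanning(win_len)
    nfft = 1 << int(math.ceil(math.log2(2 * win_len)))
    win_acf = _window_autocorrelation(window, nfft)
    # Candidates are searched well above the ceiling (up to ~1200 Hz) so a
    # tone whose true fundamental lies outside [floor, ceiling] is caught at
    # its real period and marked unvoiced, instead of being accepted at an
    # in-range sub-harmonic lag.  Max candidate lag stays at one floor
    # period (= win_len/3), where the Hann autocorrelation is still ~0.4.
    lag_min = max(2, int(math.floor(fs / 1200.0)))
    lag_max = int(math.ceil(fs / settings.pitch_floor_hz)) + 1

    global_peak = float(np.max(np.abs(x)))
    step = int(round(settings.time_step_s * fs))
    starts = np.arange(0, x.size - win_len + 1, max(step, 1))
    times = (starts + win_len / 2.0) / fs
    f0 = np.full(starts.size, np.nan)
    for k, s0 in enumerate(starts):
        frame = x[s0:s0 + win_len]
        if global_peak == 0 or np.max(np.abs(frame)) < settings.silence_threshold * global_peak:
            continue
        racf = _corrected_autocorrelation(frame, window, win_acf, nfft)
        cand = best_period_candidate(racf, lag_min, lag_max)
        if cand is None:
            continue
        lag, _ = cand
        hz = fs / lag
        if settings.pitch_floor_hz <= hz <= settings.pitch_ceiling_hz:
            f0[k] = hz
    return PitchTrack(frame_times_s=times, f0_hz=f0, settings=settings)


def pitch_stats(track: PitchTrack) -> PitchStats:
    """Mean/SD (n-1 denominator)/min/max over voiced frames; all undefined
    when no frame is voiced, SD undefined for a single voiced frame."""
    voiced = track.voiced()
    if voiced.size == 0:
        return PitchStats(UNDEFINED, UNDEFINED, UNDEFINED, UNDEFINED)
    sd = float(np.std(voiced, ddof=1)) if voiced.size > 1 else UNDEFINED
    return PitchStats(float(np.mean(voiced)), sd, float(np.min(voiced)), float(np.max(voiced)))
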