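"""Phonation trimming and glottal cycle extraction.

Cycle marks are placed at the dominant waveform peak of each expected
period window, walking outward from the strongest peak under F0 guidance
from the pitch track.  Consecutive periods are then refined to sub-sample
precision by cross-correlating each cycle's waveform against the previous
cycle (the shape of adjacent glottal cycles is nearly identical in a
sustained vowel, so the cross-correlation maximum locates the true lag
far more precisely than integer peak indices).  Per-cycle amplitudes are
peak-to-peak ranges (max - min) over the half-open span [mark_i,
mark_{i+1}) — the quantity the shimmer family is defined on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pitch import PitchTrack, _parabolic_refine
from .recording import VoiceRecording

#: Search window around the expected next peak, as a fraction of the period.
_SEARCH_FRAC = 0.3
#: Peaks below this fraction of the global maximum end the march.
_AMP_FLOOR_FRAC = 0.1
#: Half-width of the cross-correlation template, as a fraction of the period.
_XCORR_HALF_FRAC = 0.35
#: Maximum cross-correlation shift, as a fraction of the period.
_XCORR_SHIFT_FRAC = 0.2


@dataclass
class CycleSequence:
    """Per-cycle fundamental periods and peak-to-peak amplitudes."""

    cycle_times_s: np.ndarray   # N+1 cycle marks (s)
    periods_s: np.ndarray       # N periods T_i (s)
    peak_amplitudes: np.ndarray  # N peak-to-peak amplitudes A_i

    def __post_init__(self) -> None:
        if self.periods_s.size != self.peak_amplitudes.size:
            raise ValueError("periods and amplitudes must have equal length")
        if self.periods_s.size and np.any(self.periods_s <= 0):
            raise ValueError("periods must be positive")

    @property
    def n_cycles(self) -> int:
        return int(self.periods_s.size)


def _empty_cycles() -> CycleSequence:
    return CycleSequence(np.zeros(0), np.zeros(0), np.zeros(0))


def trim_phonation(rec: VoiceRecording, energy_frac: float = 0.1,
                   frame_s: float = 0.010, hop_s: float = 0.005) -> VoiceRecording:
    """Keep the contiguous span where short-time RMS exceeds
    ``energy_frac`` x the global maximum RMS.

    Automates the boundary marking of the phonation onset/offset: the
    retained span runs from the first to the last analysis frame whose
    RMS energy clears the threshold.  Idempotent on already-trimmed input.
    """
    if not 0 < energy_frac < 1:
        raise ValueError("energy_frac must be in (0, 1)")
    x = rec.samples
    fs = rec.sample_rate_hz
    frame = max(int(round(frame_s * fs)), 1)
    hop = max(int(round(hop_s * fs)), 1)
    n_frames = max((x.size - frame) // hop + 1, 1)
    idx = np.arange(n_frames) * hop
    rms = np.sqrt([np.mean(x[i:i + frame] ** 2) for i in idx])
    peak = rms.max()
    if peak == 0:
        raise ValueError("no phonation detected (silent input)")
    above = np.nonzero(rms >= energy_frac * peak)[0]
    if above.size == 0:
        raise ValueError("no phonation detected")
    # A boundary frame above threshold extends the span to the signal edge
    # (frames tile the interior; the tail may not fill a whole frame).
    start = 0 if above[0] == 0 else int(idx[above[0]])
    end = x.size if above[-1] == n_frames - 1 else int(min(idx[above[-1]] + frame, x.size))
    if start == 0 and end == x.size:
        return rec  # no-op: ground truth remains valid
    return rec.with_samples(x[start:end])


def _march_peaks(s: np.ndarray, fs: float, seed_idx: int,
                 f0_at: "np.interp", amp_floor: float) -> list[int]:
    """Integer peak marks, walking left then right from the seed peak."""
    marks = [seed_idx]
    for direction in (-1, 1):
        pos = seed_idx
        while True:
            period = fs / f0_at(pos / fs)
            center = pos + direction * period
            lo = int(round(center - _SEARCH_FRAC * period))
            hi = int(round(center + _SEARCH_FRAC * period))
            lo, hi = max(lo, 0), min(hi, s.size)
            if hi - lo < 3:
                break
            nxt = lo + int(np.argmax(s[lo:hi]))
            if s[nxt] < amp_floor:
                break
            marks.append(nxt)
            pos = nxt
    return sorted(set(marks))


def _refined_periods(s: np.ndarray, marks: list[int], fs: float) -> np.ndarray:
    """Sub-sample periods via cross-correlation of consecutive cycles.

    Period i is the integer mark difference plus the sub-sample shift that
    best aligns cycle i's waveform with cycle i-1's.
    """
    periods = np.diff(marks).astype(float)
    for i in range(1, len(marks)):
        t = periods[i - 1]
        half = int(round(_XCORR_HALF_FRAC * t))
        shift = max(int(round(_XCORR_SHIFT_FRAC * t)), 2)
        a0, a1 = marks[i - 1] - half, marks[i - 1] + half + 1
        b0, b1 = marks[i] - half - shift, marks[i] + half + shift + 1
        if a0 < 0 or b0 < 0 or b1 > s.size:
            continue
        template = s[a0:a1]
        xc = np.correlate(s[b0:b1], template, mode="valid")
        k = int(np.argmax(xc))
        dk, _ = _parabolic_refine(xc, k)
        periods[i - 1] = (marks[i] - marks[i - 1]) + (dk - shift)
    return periods / fs


def extract_cycles(rec: VoiceRecording, track: PitchTrack) -> CycleSequence:
    """Glottal cycle marks, periods and peak-to-peak amplitudes.

    Returns an empty sequence (N < 2 downstream -> "undefined") when the
    track has no voiced frames or fewer than two marks are found.
    """
    voiced = ~np.isnan(track.f0_hz)
    if not voiced.any():
        return _empty_cycles()
    x = rec.samples
    fs = rec.sample_rate_hz
    vt = track.frame_times_s[voiced]
    vf = track.f0_hz[voiced]

    def f0_at(t: float) -> float:
        return float(np.interp(t, vt, vf))

    # Work on the polarity that makes the dominant excursion positive.
    s = x if abs(x.max()) >= abs(x.min()) else -x
    lo = int(max((vt[0] - 0.5 / f0_at(vt[0])) * fs, 0))
    hi = int(min((vt[-1] + 0.5 / f0_at(vt[-1])) * fs, x.size))
    if hi - lo < 3:
        return _empty_cycles()
    seed = lo + int(np.argmax(s[lo:hi]))
    amp_floor = _AMP_FLOOR_FRAC * float(s[seed])
    marks = _march_peaks(s, fs, seed, f0_at, amp_floor)
    if len(marks) < 2:
        return _empty_cycles()

    periods = _refined_periods(s, marks, fs)
    # Peak-to-peak amplitude of cycle i is measured in a window centered on
    # its own mark and strictly inside the neighboring periods, so that one
    # cycle's amplitude never bleeds into the next.
    amps = np.zeros(len(marks) - 1)
    for i in range(len(marks) - 1):
        left = marks[i] - marks[i - 1] if i > 0 else marks[i + 1] - marks[i]
        right = marks[i + 1] - marks[i]
        a0 = max(marks[i] - int(0.4 * left), 0)
        a1 = min(marks[i] + int(0.4 * right) + 1, x.size)
        amps[i] = float(np.ptp(x[a0:a1]))
    # Refine mark times to sub-sample precision for reporting.
    mark_times = np.array([_parabolic_refine(s, m)[0] for m in marks]) / fs
    return CycleSequence(cycle_times_s=mark_times, periods_s=periods, peak_amplitudes=amps)
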