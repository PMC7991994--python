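"""Jitter and shimmer families over an extracted cycle sequence.

Given fundamental periods T_1..T_N (s) and per-cycle peak-to-peak
amplitudes A_1..A_N, this module evaluates the classical perturbation
measures:

* jitter(absolute)   mean |T_i - T_{i-1}| over admissible pairs (s)
* jitter(relative)   jitter(absolute) / mean(T) x 100 (%)
* jitter(rap)        mean |T_i - mean(T_{i-1},T_i,T_{i+1})| / mean(T) x 100
* jitter(ppq5)       five-point period perturbation quotient (%)
* shimmer(dB)        mean 20|log10(A_i / A_{i-1})| over admissible pairs
* shimmer(relative)  mean |A_i - A_{i-1}| / mean(A) x 100 (%)
* shimmer(apq3/5/11) n-point amplitude perturbation quotients (%)

Exclusion rules: a period outside [period_floor, period_ceiling] is out of
range; a consecutive pair whose period ratio exceeds the maximum period
factor is not counted, and the effective cycle count drops by one for each
excluded term.  When fewer than two effective cycles remain (or a quotient
has no complete window) the result is the distinguished value "undefined",
represented as NaN and carried through, never silently replaced.

ppq/apq windows must fit entirely inside the sequence (interior indices
only) and require every period in the window to be in range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

UNDEFINED = math.nan


def is_defined(x: float) -> bool:
    return not math.isnan(x)


@dataclass
class PerturbationSettings:
    """Admissibility rules for cycles entering jitter/shimmer."""

    period_floor_s: float = 0.002
    period_ceiling_s: float = 0.025
    max_period_factor: float = 1.3

    def __post_init__(self) -> None:
        if not 0 < self.period_floor_s < self.period_ceiling_s:
            raise ValueError("need 0 < period_floor_s < period_ceiling_s")
        if not self.max_period_factor > 1:
            raise ValueError("max_period_factor must be > 1")


class JitterResult(NamedTuple):
    absolute_s: float
    relative_pct: float
    rap_pct: float
    ppq5_pct: float


class ShimmerResult(NamedTuple):
    db: float
    relative_pct: float
    apq3_pct: float
    apq5_pct: float
    apq11_pct: float


def in_range_mask(periods_s: np.ndarray, settings: PerturbationSettings) -> np.ndarray:
    periods_s = np.asarray(periods_s, dtype=float)
    return (periods_s >= settings.period_floor_s) & (periods_s <= settings.period_ceiling_s)


def valid_pair_mask(periods_s: np.ndarray, settings: PerturbationSettings) -> np.ndarray:
    """Validity of each consecutive pair (T_{i-1}, T_i), length N-1.

    A pair is valid iff both periods lie within [floor, ceiling] and the
    larger/smaller period ratio does not exceed the maximum period factor.
    """
    periods_s = np.asarray(periods_s, dtype=float)
    if periods_s.size < 2:
        return np.zeros(max(periods_s.size - 1, 0), dtype=bool)
    ok = in_range_mask(periods_s, settings)
    prev, cur = periods_s[:-1], periods_s[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.maximum(cur / prev, prev / cur)
    return ok[:-1] & ok[1:] & (factor <= settings.max_period_factor)


def _window_mask(ok: np.ndarray, width: int) -> np.ndarray:
    """Validity of each centered window of ``width`` in-range periods;
    True at center index i iff all of ok[i-h .. i+h] (h = width//2)."""
    n = ok.size
    h = width // 2
    centers = np.arange(h, n - h)
    if centers.size == 0:
        return np.zeros(0, dtype=bool), centers
    valid = np.ones(centers.size, dtype=bool)
    for off in range(-h, h + 1):
        valid &= ok[centers + off]
    return valid, centers


def _mean_in_range(values: np.ndarray, ok: np.ndarray) -> float:
    if not ok.any():
        return UNDEFINED
    return float(np.mean(values[ok]))


def _quotient(values: np.ndarray, ok: np.ndarray, width: int, grand_mean: float) -> float:
    """n-point perturbation quotient (%): mean |v_i - window mean| / grand mean."""
    valid, centers = _window_mask(ok, width)
    if not np.any(valid) or not is_defined(grand_mean) or grand_mean == 0:
        return UNDEFINED
    h = width // 2
    centers = centers[valid]
    window_means = np.zeros(centers.size)
    for off in range(-h, h + 1):
        window_means += values[centers + off]
    window_means /= width
    return float(np.mean(np.abs(values[centers] - window_means)) / grand_mean * 100.0)


def jitter_features(periods_s: np.ndarray, settings: PerturbationSettings) -> JitterResult:
    """All four jitter variants; NaN marks "undefined"."""
    periods_s = np.asarray(periods_s, dtype=float)
    n = periods_s.size
    if n < 2:
        return JitterResult(UNDEFINED, UNDEFINED, UNDEFINED, UNDEFINED)
    ok = in_range_mask(periods_s, settings)
    pairs = valid_pair_mask(periods_s, settings)
    mean_t = _mean_in_range(periods_s, ok)

    # Each excluded pair term lowers the effective N by one; fewer than two
    # effective cycles -> undefined.  With N periods and m valid pair terms,
    # effective N = m + 1.
    m = int(pairs.sum())
    if m < 1 or not is_defined(mean_t):
        absolute = UNDEFINED
        relative = UNDEFINED
    else:
        diffs = np.abs(np.diff(periods_s))[pairs]
        absolute = float(np.mean(diffs))
        relative = absolute / mean_t * 100.0

    rap = _quotient(periods_s, ok, 3, mean_t)
    ppq5 = _quotient(periods_s, ok, 5, mean_t)
    return JitterResult(absolute, relative, rap, ppq5)


def shimmer_features(periods_s: np.ndarray, amplitudes: np.ndarray,
                     settings: PerturbationSettings) -> ShimmerResult:
    """All five shimmer variants; pair/window admissibility is governed by
    the periods exactly as for jitter.  NaN marks "undefined"."""
    periods_s = np.asarray(periods_s, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if periods_s.shape != amplitudes.shape:
        raise ValueError("periods and amplitudes must have equal length")
    n = periods_s.size
    if n < 2:
        return ShimmerResult(*([UNDEFINED] * 5))
    if np.any(amplitudes <= 0):
        raise ValueError("non-positive peak-to-peak amplitude (log undefined)")
    ok = in_range_mask(periods_s, settings)
    pairs = valid_pair_mask(periods_s, settings)
    mean_a = _mean_in_range(amplitudes, ok)

    m = int(pairs.sum())
    if m < 1 or not is_defined(mean_a) or mean_a == 0:
        db = UNDEFINED
        relative = UNDEFINED
    else:
        ratio = amplitudes[1:] / amplitudes[:-1]
        db = float(np.mean(20.0 * np.abs(np.log10(ratio[pairs]))))
        relative = float(np.mean(np.abs(np.diff(amplitudes))[pairs]) / mean_a * 100.0)

    apq3 = _quotient(amplitudes, ok, 3, mean_a)
    apq5 = _quotient(amplitudes, ok, 5, mean_a)
    apq11 = _quotient(amplitudes, ok, 11, mean_a)
    return ShimmerResult(db, relative, apq3, apq5, apq11)
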