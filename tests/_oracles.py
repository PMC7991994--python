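"""Independent brute-force oracles for the perturbation equations.

Deliberately written as plain Python loops, straight from the printed
definitions of the jitter/shimmer families, sharing no code with the
package implementation.  NaN encodes "undefined".
"""

import math


def _in_range(t, floor, ceiling):
    return floor <= t <= ceiling


def _mean_in_range(values, periods, floor, ceiling):
    kept = [v for v, t in zip(values, periods) if _in_range(t, floor, ceiling)]
    if not kept:
        return math.nan
    return sum(kept) / len(kept)


def _pair_ok(a, b, floor, ceiling, mpf):
    if not (_in_range(a, floor, ceiling) and _in_range(b, floor, ceiling)):
        return False
    return max(a / b, b / a) <= mpf


def brute_jitter(periods, floor=0.002, ceiling=0.025, mpf=1.3):
    """(absolute_s, relative_pct, rap_pct, ppq5_pct) by direct evaluation."""
    n = len(periods)
    nan4 = (math.nan,) * 4
    if n < 2:
        return nan4
    mean_t = _mean_in_range(periods, periods, floor, ceiling)

    diffs = [abs(periods[i] - periods[i - 1]) for i in range(1, n)
             if _pair_ok(periods[i - 1], periods[i], floor, ceiling, mpf)]
    if diffs and not math.isnan(mean_t):
        absolute = sum(diffs) / len(diffs)
        relative = absolute / mean_t * 100.0
    else:
        absolute = relative = math.nan

    def quotient(width):
        h = width // 2
        terms = []
        for i in range(h, n - h):
            window = periods[i - h:i + h + 1]
            if all(_in_range(t, floor, ceiling) for t in window):
                terms.append(abs(periods[i] - sum(window) / width))
        if not terms or math.isnan(mean_t) or mean_t == 0:
            return math.nan
        return (sum(terms) / len(terms)) / mean_t * 100.0

    return absolute, relative, quotient(3), quotient(5)


def brute_shimmer(periods, amps, floor=0.002, ceiling=0.025, mpf=1.3):
    """(db, relative_pct, apq3, apq5, apq11) by direct evaluation; pair and
    window admissibility are driven by the periods, as for jitter."""
    n = len(periods)
    if n < 2:
        return (math.nan,) * 5
    mean_a = _mean_in_range(amps, periods, floor, ceiling)

    db_terms, rel_terms = [], []
    for i in range(1, n):
        if _pair_ok(periods[i - 1], periods[i], floor, ceiling, mpf):
            db_terms.append(20.0 * abs(math.log10(amps[i] / amps[i - 1])))
            rel_terms.append(abs(amps[i] - amps[i - 1]))
    if db_terms and not math.isnan(mean_a) and mean_a != 0:
        db = sum(db_terms) / len(db_terms)
        relative = (sum(rel_terms) / len(rel_terms)) / mean_a * 100.0
    else:
        db = relative = math.nan

    def quotient(width):
        h = width // 2
        terms = []
        for i in range(h, n - h):
            if all(_in_range(t, floor, ceiling) for t in periods[i - h:i + h + 1]):
                window = amps[i - h:i + h + 1]
                terms.append(abs(amps[i] - sum(window) / width))
        if not terms or math.isnan(mean_a) or mean_a == 0:
            return math.nan
        return (sum(terms) / len(terms)) / mean_a * 100.0

    return db, relative, quotient(3), quotient(5), quotient(11)
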