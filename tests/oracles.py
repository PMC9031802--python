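"""Independent brute-force oracles used to cross-check the pipeline.

These are deliberately literal, loop-based implementations of the rules
(and of block matching / sorting), kept free of any code from the package
under test.
"""

from __future__ import annotations

import math

import numpy as np


def block_match_shift(prev: np.ndarray, nxt: np.ndarray, max_shift: int = 3):
    """Exhaustive integer-shift search minimizing SSD under wrap-around."""
    best = None
    best_score = math.inf
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            shifted = np.roll(np.roll(prev, dy, axis=0), dx, axis=1)
            score = float(((shifted - nxt) ** 2).sum())
            if score < best_score:
                best_score = score
                best = (dx, dy)
    return best  # (u, v) convention: x right, y down


def top_fraction_mean_sorted(u: np.ndarray, v: np.ndarray, fraction: float):
    """Full-sort reference for the top-fraction magnitude mean."""
    mags = sorted(
        math.hypot(a, b) for a, b in zip(u.ravel().tolist(), v.ravel().tolist())
    )
    k = max(1, int(math.floor(fraction * len(mags))))
    return sum(mags[-k:]) / k


def percentile_linear(values, p: float) -> float:
    """Linear-interpolation percentile, written out longhand."""
    s = sorted(float(x) for x in values)
    if len(s) == 1:
        return s[0]
    h = (len(s) - 1) * p / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def literal_peak_rules(
    values,
    baseline_percentile: float = 10.0,
    min_rel_amplitude: float = 0.05,
    endpoint_frac: float = 0.20,
):
    """Literal application of the peak rules: percentile baseline, local
    maxima, relative amplitude filter, outward endpoint scan with linear
    interpolation rounded to the nearest sample.

    Returns (baseline, [(start, apex, end), ...]).
    """
    v = [float(x) for x in values]
    n = len(v)
    base = percentile_linear(v, baseline_percentile)

    apexes = []
    i = 1
    while i < n - 1:
        if v[i] > v[i - 1]:
            j = i
            while j < n - 1 and v[j + 1] == v[i]:
                j += 1
            if j < n - 1 and v[j + 1] < v[i]:
                apexes.append((i + j) // 2)
            i = j + 1
        else:
            i += 1

    apexes = [a for a in apexes if v[a] > base]
    if not apexes:
        return base, []
    biggest = max(v[a] - base for a in apexes)
    kept = [a for a in apexes if v[a] - base >= min_rel_amplitude * biggest]

    peaks = []
    for idx, apex in enumerate(kept):
        level = base + endpoint_frac * (v[apex] - base)
        lo_limit = kept[idx - 1] if idx > 0 else 0
        hi_limit = kept[idx + 1] if idx < len(kept) - 1 else n - 1

        start = lo_limit
        j = apex
        while j > lo_limit:
            if v[j - 1] <= level:
                frac = j - (v[j] - level) / (v[j] - v[j - 1])
                start = int(round(frac))
                break
            j -= 1

        end = hi_limit
        j = apex
        while j < hi_limit:
            if v[j + 1] <= level:
                frac = j + (v[j] - level) / (v[j] - v[j + 1])
                end = int(round(frac))
                break
            j += 1
        peaks.append((start, apex, end))
    return base, peaks


def literal_pairing(peak_triples, max_gap_s: float, dt: float):
    """Greedy left-to-right pairing on (start, apex, end) triples."""
    events = []
    unmatched = []
    i = 0
    while i < len(peak_triples):
        if i + 1 < len(peak_triples):
            gap = (peak_triples[i + 1][0] - peak_triples[i][2]) * dt
            if 0 <= gap <= max_gap_s:
                events.append((peak_triples[i], peak_triples[i + 1]))
                i += 2
                continue
        unmatched.append(peak_triples[i])
        i += 1
    return events, unmatched


def random_piecewise_linear_trace(rng: np.random.Generator, n: int = 200):
    """A random piecewise-linear trace with a handful of knots."""
    n_knots = rng.integers(4, 12)
    xs = np.sort(rng.choice(np.arange(1, n - 1), size=n_knots, replace=False))
    xs = np.concatenate([[0], xs, [n - 1]])
    ys = rng.uniform(0, 100, size=xs.size)
    return np.interp(np.arange(n), xs, ys)
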