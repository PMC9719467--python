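"""Brute-force reference implementation of the activity-detection rules.

Deliberately literal and loop-based, independent of the package internals:
window RMS values are computed one slice at a time, and event formation
follows the verbal procedure (seed runs longer than 0.1 s, then repeated
absorption of neighbouring bout runs across gaps shorter than 0.25 s until
a fixed point).  Used as the oracle for exact-equivalence tests.
"""

from __future__ import annotations

import math

import numpy as np


def window_rms(x, fs, step=0.015, window=0.030):
    """List of (start_index_on_grid, rms) for every full sliding window."""
    nwin = round(window * fs)
    out = []
    i = 0
    while True:
        s = round(i * step * fs)
        if s + nwin > len(x):
            break
        seg = x[s:s + nwin]
        out.append(math.sqrt(sum(float(v) * float(v) for v in seg) / nwin))
        i += 1
    return out


def bout_flags(rms_values, baseline, factor=2.0):
    return [v > factor * baseline for v in rms_values]


def events_from_flags(flags, step=0.015, min_bout=0.1, max_gap=0.25):
    """Event intervals (seconds, slab convention) via literal rule-following."""
    runs = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    seeds = [k for k, (s, e) in enumerate(runs)
             if (e - s) * step > min_bout + 1e-9]
    events = set()
    for k in seeds:
        lo = hi = k
        changed = True
        while changed:
            changed = False
            if lo > 0 and (runs[lo][0] - runs[lo - 1][1]) * step \
                    < max_gap - 1e-9:
                lo -= 1
                changed = True
            if hi + 1 < len(runs) and (runs[hi + 1][0] - runs[hi][1]) * step \
                    < max_gap - 1e-9:
                hi += 1
                changed = True
        events.add((runs[lo][0], runs[hi][1]))
    return sorted((s * step, e * step) for s, e in events)


def detect_events(x, fs, baseline, step=0.015, window=0.030,
                  factor=2.0, min_bout=0.1, max_gap=0.25):
    """Full reference chain: windows -> flags -> events."""
    rms = window_rms(x, fs, step, window)
    flags = bout_flags(rms, baseline, factor)
    return events_from_flags(flags, step, min_bout, max_gap)


def enumerate_clean_windows(runs, window, step=0.015):
    """All window start times fully inside artefact-free runs (brute force)."""
    out = []
    for s, e in runs:
        t = s
        while t + window <= e + 1e-9:
            out.append(t)
            t += step
    return out


def rolling_rms_brute(x, fs, window, step=0.015):
    """(start_time, rms) pairs of the rolling window, loop implementation."""
    nwin = round(window * fs)
    out = []
    i = 0
    while True:
        s = round(i * step * fs)
        if s + nwin > len(x):
            break
        seg = np.asarray(x[s:s + nwin], dtype=float)
        out.append((i * step, float(np.sqrt(np.mean(seg * seg)))))
        i += 1
    return out
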