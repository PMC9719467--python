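"""Half-open interval algebra on float seconds.

All intervals are ``(start, end)`` with ``end > start``; degenerate or
reversed intervals are dropped.  Used for artefact masks, REM segments and
activity events throughout the package.
"""

from __future__ import annotations

import numpy as np


def as_array(intervals) -> np.ndarray:
    """Coerce a sequence of (start, end) pairs to an (n, 2) float array."""
    a = np.asarray(intervals, dtype=float)
    if a.size == 0:
        return np.empty((0, 2))
    a = a.reshape(-1, 2)
    return a[a[:, 1] > a[:, 0]]


def merge(intervals) -> np.ndarray:
    """Sort and merge overlapping or touching intervals."""
    a = as_array(intervals)
    if len(a) == 0:
        return a
    a = a[np.argsort(a[:, 0])]
    out = [list(a[0])]
    for s, e in a[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out)


def clip(intervals, lo: float, hi: float) -> np.ndarray:
    """Intersect every interval with the window [lo, hi]."""
    a = as_array(intervals)
    if len(a) == 0:
        return a
    a = a.copy()
    a[:, 0] = np.maximum(a[:, 0], lo)
    a[:, 1] = np.minimum(a[:, 1], hi)
    return a[a[:, 1] > a[:, 0]]


def intersect(a, b) -> np.ndarray:
    """Pairwise intersection of two merged interval sets."""
    a, b = merge(a), merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if e > s:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return as_array(out)


def complement(intervals, lo: float, hi: float) -> np.ndarray:
    """Gaps of `intervals` within [lo, hi]."""
    a = merge(clip(intervals, lo, hi))
    out = []
    cur = lo
    for s, e in a:
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if hi > cur:
        out.append((cur, hi))
    return as_array(out)


def total(intervals) -> float:
    a = merge(intervals)
    return float(np.sum(a[:, 1] - a[:, 0])) if len(a) else 0.0


def overlaps(intervals, lo: float, hi: float) -> bool:
    """True if any interval intersects the open window (lo, hi)."""
    return len(clip(intervals, lo, hi)) > 0
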