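"""REM segments and per-channel artefact masks.

Maximal runs of consecutive REM epochs become segments; runs of at least
150 s are "REM periods" (they get their own baseline), shorter runs are
"REM bouts" (they inherit one).  Artefacts -- scored arousal/respiratory
events on every channel, snore events on the chin only, and electrode
detachment detected from the signal -- are kept as exact interval sets
rather than a sampled boolean series, clipped to REM time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _intervals as iv
from .io_formats import EmgChannel, EventKind, EventList, Hypnogram, Role, \
    SNORE_SENSITIVE, Stage
from .preprocess import DetectionParams


@dataclass(frozen=True)
class RemSegment:
    start: float
    end: float
    is_period: bool

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def extract_rem_segments(hypnogram: Hypnogram,
                         params: DetectionParams) -> list[RemSegment]:
    """Maximal runs of consecutive REM epochs, flagged by the 150 s rule.

    Epochs separated by a gap in the hypnogram are not considered
    consecutive.  Returns an empty list when no REM was scored.
    """
    segments: list[RemSegment] = []
    run_start = None
    prev_end = None
    for onset, stage in zip(hypnogram.onsets, hypnogram.stages):
        is_rem = stage is Stage.REM
        contiguous = prev_end is not None and abs(onset - prev_end) < 1e-6
        if is_rem and run_start is not None and contiguous:
            prev_end = onset + hypnogram.epoch_len
        elif is_rem:
            if run_start is not None:
                segments.append(_make_segment(run_start, prev_end, params))
            run_start = onset
            prev_end = onset + hypnogram.epoch_len
        else:
            if run_start is not None:
                segments.append(_make_segment(run_start, prev_end, params))
                run_start = None
            prev_end = onset + hypnogram.epoch_len
    if run_start is not None:
        segments.append(_make_segment(run_start, prev_end, params))
    return segments


def _make_segment(start: float, end: float,
                  params: DetectionParams) -> RemSegment:
    return RemSegment(start=start, end=end,
                      is_period=(end - start) >= params.min_rem_period)


def detect_detachment(channel: EmgChannel, segment: RemSegment,
                      params: DetectionParams) -> np.ndarray:
    """Spans whose rolling RMS falls below the detachment threshold.

    A channel that reads below 0.05 mV RMS over the baseline window length
    is considered detached (sustained silence, not a momentary dip).  The
    window is stepped on the detection grid and each sub-threshold window
    flags its own span; overlapping flagged windows merge.  For segments
    shorter than the window the whole segment is evaluated at once.
    """
    fs = channel.fs
    i0 = int(round(segment.start * fs))
    i1 = min(int(round(segment.end * fs)), len(channel.samples))
    x = channel.samples[i0:i1]
    if len(x) == 0:
        return np.empty((0, 2))
    win = min(params.baseline_window, segment.duration)
    nwin = max(1, int(round(win * fs)))
    starts = _grid_starts(len(x), nwin, params.rms_step, fs)
    cs = np.concatenate([[0.0], np.cumsum(x * x)])
    rms = np.sqrt((cs[starts + nwin] - cs[starts]) / nwin)
    low = rms < params.detachment_rms
    spans = [(segment.start + s / fs, segment.start + (s + nwin) / fs)
             for s, flag in zip(starts, low) if flag]
    return iv.clip(iv.merge(spans), segment.start, segment.end)


def _grid_starts(n: int, nwin: int, step_s: float, fs: float) -> np.ndarray:
    """Window start indices on the step grid with full windows only."""
    if n < nwin:
        return np.empty(0, dtype=int)
    # generous upper bound, then keep exactly the full windows (start-index
    # rounding can admit one more window than the naive count)
    n_steps = int(np.floor((n - nwin) / (step_s * fs))) + 3
    starts = np.round(np.arange(n_steps) * step_s * fs).astype(int)
    return starts[starts + nwin <= n]


@dataclass
class ArtefactMask:
    """Excluded time for one channel, clipped to its REM segments."""

    role: Role
    segments: list[RemSegment]
    intervals: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2)))   # merged, within REM

    def free_runs(self, segment: RemSegment) -> np.ndarray:
        """Maximal artefact-free intervals inside `segment`."""
        return iv.complement(self.intervals, segment.start, segment.end)

    def is_clean(self, lo: float, hi: float) -> bool:
        """True if [lo, hi] contains no masked time."""
        return not iv.overlaps(self.intervals, lo, hi)

    @property
    def masked_time(self) -> float:
        return iv.total(self.intervals)

    @property
    def rem_time(self) -> float:
        return sum(s.duration for s in self.segments)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.intervals, columns=["start_s", "end_s"])


def build_artefact_mask(segments: list[RemSegment],
                        events: dict[EventKind, EventList] | list[EventList],
                        detachment: np.ndarray | None,
                        role: Role) -> ArtefactMask:
    """Union of applicable event intervals and detachment, clipped to REM.

    Arousal and respiratory events are excluded on every channel; snore
    events only on snore-sensitive (chin) channels.
    """
    if isinstance(events, dict):
        events = list(events.values())
    pieces = []
    for ev in events:
        if ev.kind is EventKind.SNORE and role not in SNORE_SENSITIVE:
            continue
        if len(ev):
            pieces.append(ev.intervals)
    if detachment is not None and len(detachment):
        pieces.append(np.asarray(detachment, dtype=float))
    if pieces:
        merged = iv.merge(np.vstack(pieces))
        clipped = [iv.clip(merged, s.start, s.end) for s in segments]
        intervals = iv.merge(np.vstack([c for c in clipped if len(c)])
                             if any(len(c) for c in clipped)
                             else np.empty((0, 2)))
    else:
        intervals = np.empty((0, 2))
    return ArtefactMask(role=role, segments=list(segments),
                        intervals=intervals)
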