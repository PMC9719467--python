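"""Per-REM-period baseline amplitude estimation and propagation.

Each REM period is assigned the lowest RMS of a 30 s rolling window taken
entirely within artefact-free time; if no clean 30 s window exists the
search is repeated with 15 s windows.  Periods still without a baseline
inherit from the previous period with a measured one (else the next), and
REM bouts shorter than 150 s take the baseline of the nearest period.  A
channel with no measurable baseline anywhere is discarded from scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .io_formats import EmgChannel, Role
from .preprocess import DetectionParams
from .rem_segmentation import ArtefactMask, RemSegment, _grid_starts


class BaselineSource(str, Enum):
    WINDOW30 = "window30"
    WINDOW15 = "window15"
    INHERITED_PREV = "inherited_prev"
    INHERITED_NEXT = "inherited_next"
    NEAREST_SEGMENT = "nearest_segment"
    UNAVAILABLE = "unavailable"


MEASURED = {BaselineSource.WINDOW30, BaselineSource.WINDOW15}


class ChannelDiscardedWarning(UserWarning):
    """Raised (as a warning) when a channel has no measurable baseline."""

    def __init__(self, role: Role, reason: str):
        super().__init__(f"channel {role.value} discarded: {reason}")
        self.role = role
        self.reason = reason


@dataclass
class BaselineAssignment:
    """Baseline amplitude (RMS, mV) and provenance for every REM segment."""

    segments: list[RemSegment]
    amplitudes: list[float]            # NaN iff source is UNAVAILABLE
    sources: list[BaselineSource]

    def for_segment(self, segment: RemSegment) -> float:
        return self.amplitudes[self.segments.index(segment)]

    @property
    def usable(self) -> bool:
        return any(s is not BaselineSource.UNAVAILABLE for s in self.sources)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "start_s": [s.start for s in self.segments],
            "end_s": [s.end for s in self.segments],
            "is_period": [s.is_period for s in self.segments],
            "baseline_mv": self.amplitudes,
            "source": [s.value for s in self.sources],
        })


def _min_window_rms(channel: EmgChannel, runs: np.ndarray, window: float,
                    params: DetectionParams) -> float:
    """Lowest RMS over all full `window`-length windows inside clean runs."""
    fs = channel.fs
    best = np.inf
    nwin = int(round(window * fs))
    for run_start, run_end in runs:
        i0 = int(round(run_start * fs))
        i1 = min(int(round(run_end * fs)), len(channel.samples))
        x = channel.samples[i0:i1]
        starts = _grid_starts(len(x), nwin, params.rms_step, fs)
        if len(starts) == 0:
            continue
        cs = np.concatenate([[0.0], np.cumsum(x * x)])
        rms = np.sqrt((cs[starts + nwin] - cs[starts]) / nwin)
        best = min(best, float(rms.min()))
    return best


def estimate_baseline(channel: EmgChannel, segment: RemSegment,
                      mask: ArtefactMask, params: DetectionParams
                      ) -> tuple[float, BaselineSource]:
    """Measure the baseline of one REM period.

    "Continuously artefact-free" means the whole window contains no masked
    time of this channel.  Returns NaN with source ``unavailable`` when
    neither the 30 s nor the 15 s window search succeeds.
    """
    if not segment.is_period:
        raise ValueError("baselines are measured on REM periods only")
    runs = mask.free_runs(segment)
    for window, source in ((params.baseline_window, BaselineSource.WINDOW30),
                           (params.baseline_window_fallback,
                            BaselineSource.WINDOW15)):
        best = _min_window_rms(channel, runs, window, params)
        if np.isfinite(best) and best > 0:
            return best, source
    return float("nan"), BaselineSource.UNAVAILABLE


def propagate_baseline(segments: list[RemSegment],
                       measured: list[tuple[float, BaselineSource]],
                       role: Role = Role.OTHER) -> BaselineAssignment:
    """Complete the assignment across periods and bouts.

    Periods without a measured baseline inherit transitively from the
    previous measured period, else from the next.  Bouts (< 150 s) take the
    baseline of the nearest period by midpoint distance, ties to the
    earlier period.  Emits :class:`ChannelDiscardedWarning` when nothing is
    measurable anywhere.
    """
    if len(segments) != len(measured):
        raise ValueError("one measured entry per segment required")
    amplitudes = [m[0] for m in measured]
    sources = [m[1] for m in measured]

    periods = [i for i, s in enumerate(segments) if s.is_period]
    anchored = [i for i in periods if sources[i] in MEASURED]
    if not anchored:
        warnings.warn(ChannelDiscardedWarning(
            role, "no artefact-free baseline window in any REM period"))
        return BaselineAssignment(
            segments=list(segments),
            amplitudes=[float("nan")] * len(segments),
            sources=[BaselineSource.UNAVAILABLE] * len(segments))

    for i in periods:
        if sources[i] in MEASURED:
            continue
        prev = [j for j in anchored if j < i]
        if prev:
            amplitudes[i] = amplitudes[prev[-1]]
            sources[i] = BaselineSource.INHERITED_PREV
        else:
            nxt = [j for j in anchored if j > i]
            amplitudes[i] = amplitudes[nxt[0]]
            sources[i] = BaselineSource.INHERITED_NEXT

    for i, seg in enumerate(segments):
        if seg.is_period:
            continue
        # nearest period by midpoint distance; tie -> earlier period
        dists = [(abs(segments[j].midpoint - seg.midpoint),
                  segments[j].start, j) for j in periods]
        _, _, j = min(dists)
        amplitudes[i] = amplitudes[j]
        sources[i] = BaselineSource.NEAREST_SEGMENT

    return BaselineAssignment(segments=list(segments),
                              amplitudes=amplitudes, sources=sources)


def assign_baselines(channel: EmgChannel, segments: list[RemSegment],
                     mask: ArtefactMask, params: DetectionParams
                     ) -> BaselineAssignment:
    """Estimate on every period, then propagate to all segments."""
    measured = []
    for seg in segments:
        if seg.is_period:
            measured.append(estimate_baseline(channel, seg, mask, params))
        else:
            measured.append((float("nan"), BaselineSource.UNAVAILABLE))
    return propagate_baseline(segments, measured, role=channel.role)
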