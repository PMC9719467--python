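"""Core SINBAR scorer: RMS track, activity events, tonic/phasic/any flags.

The detector works on a 15 ms grid: the RMS of a 30 ms sliding window is
evaluated every 15 ms, each value standing for one 15 ms slab of time.
Slabs whose RMS strictly exceeds twice the baseline amplitude are "activity
bouts"; maximal runs of bouts lasting more than 0.1 s seed "activity
events", which absorb neighbouring bout runs across sub-threshold gaps
shorter than 0.25 s until a gap of at least 0.25 s ends the event.

A 30 s REM epoch is tonic when increased activity covers at least half of
it; the epoch's baseline is then elevated to the RMS of the activity spans
and phasic scoring inside that epoch is repeated against the elevated
baseline, so only bouts at twice the background tonic level survive.
Phasic events (<= 5 s) and intermediate events (5-15 s) mark the 3 s
mini-epochs they overlap; "any" activity combines phasic, intermediate,
and all mini-epochs of tonic epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from . import _intervals as iv
from .baseline_estimation import BaselineAssignment, BaselineSource, \
    assign_baselines
from .io_formats import EmgChannel, EventKind, EventList, Hypnogram, \
    RecordingSet, Role, Stage
from .preprocess import DetectionParams, bandlimit, resample
from .rem_segmentation import ArtefactMask, RemSegment, _grid_starts, \
    build_artefact_mask, detect_detachment, extract_rem_segments

_EPS = 1e-9


class Category(str, Enum):
    PHASIC = "phasic"
    INTERMEDIATE = "intermediate"
    TONIC = "tonic"


def classify(duration: float, params: DetectionParams) -> Category:
    if duration <= params.phasic_max + _EPS:
        return Category.PHASIC
    if duration <= params.intermediate_max + _EPS:
        return Category.INTERMEDIATE
    return Category.TONIC


@dataclass(frozen=True)
class ActivityEvent:
    """One contiguous interval of increased EMG activity."""

    channel: Role
    start: float
    end: float
    category: Category
    max_amplitude: float      # peak RMS-track value inside the event, mV

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class RmsTrack:
    """Sliding-window RMS values on the 15 ms grid of one artefact-free run."""

    values: np.ndarray
    t0: float
    step: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) * self.step

    def max_in(self, lo: float, hi: float) -> float:
        t = self.times()
        sel = (t + self.step > lo) & (t < hi)
        return float(self.values[sel].max()) if sel.any() else float("nan")


def compute_rms_track(channel: EmgChannel, start: float, end: float,
                      params: DetectionParams) -> RmsTrack:
    """RMS of the 30 ms window stepped at 15 ms over [start, end).

    The final partial window is dropped; a run shorter than one window
    yields an empty track.
    """
    fs = channel.fs
    i0 = int(round(start * fs))
    i1 = min(int(round(end * fs)), len(channel.samples))
    x = channel.samples[i0:i1]
    nwin = int(round(params.rms_window * fs))
    starts = _grid_starts(len(x), nwin, params.rms_step, fs)
    if len(starts) == 0:
        return RmsTrack(values=np.empty(0), t0=start, step=params.rms_step)
    cs = np.concatenate([[0.0], np.cumsum(x * x)])
    rms = np.sqrt((cs[starts + nwin] - cs[starts]) / nwin)
    return RmsTrack(values=rms, t0=start, step=params.rms_step)


def detect_activity_bouts(track: RmsTrack, baseline: float,
                          params: DetectionParams) -> np.ndarray:
    """Boolean flags: RMS strictly exceeding threshold_factor x baseline."""
    if not baseline > 0:
        raise ValueError("baseline must be positive")
    return track.values > params.threshold_factor * baseline


def merge_into_events(flags: np.ndarray, params: DetectionParams,
                      t0: float = 0.0) -> np.ndarray:
    """Build increased-activity intervals from bout flags.

    Maximal true-runs longer than ``min_bout`` (strict) seed events; runs
    separated by sub-threshold gaps shorter than ``max_gap`` are connected
    (iterated to the fixed point), and a connected group forms an event iff
    it contains a seed.  Returns (n, 2) start/end seconds; boundaries lie
    on the 15 ms slab grid.
    """
    flags = np.asarray(flags, dtype=bool)
    step = params.rms_step
    d = np.diff(np.concatenate([[0], flags.astype(np.int8), [0]]))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)          # exclusive
    if len(run_starts) == 0:
        return np.empty((0, 2))
    seeds = (run_ends - run_starts) * step > params.min_bout + _EPS
    events = []
    grp_start, grp_end, grp_seed = run_starts[0], run_ends[0], seeds[0]
    for s, e, seed in zip(run_starts[1:], run_ends[1:], seeds[1:]):
        gap = (s - grp_end) * step
        if gap < params.max_gap - _EPS:
            grp_end, grp_seed = e, grp_seed or seed
        else:
            if grp_seed:
                events.append((t0 + grp_start * step, t0 + grp_end * step))
            grp_start, grp_end, grp_seed = s, e, seed
    if grp_seed:
        events.append((t0 + grp_start * step, t0 + grp_end * step))
    return iv.as_array(events)


def _events_in_run(channel: EmgChannel, run_start: float, run_end: float,
                   baseline: float, params: DetectionParams
                   ) -> list[ActivityEvent]:
    track = compute_rms_track(channel, run_start, run_end, params)
    if len(track.values) == 0:
        return []
    flags = detect_activity_bouts(track, baseline, params)
    spans = merge_into_events(flags, params, t0=run_start)
    return [ActivityEvent(channel=channel.role, start=s, end=e,
                          category=classify(e - s, params),
                          max_amplitude=track.max_in(s, e))
            for s, e in spans]


def _signal_rms(channel: EmgChannel, spans: np.ndarray) -> float:
    """RMS of the raw samples over a union of time intervals."""
    fs = channel.fs
    acc, n = 0.0, 0
    for s, e in spans:
        i0 = int(round(s * fs))
        i1 = min(int(round(e * fs)), len(channel.samples))
        x = channel.samples[i0:i1]
        acc += float(np.sum(x * x))
        n += len(x)
    return float(np.sqrt(acc / n)) if n else float("nan")


def score_tonic(epoch_start: float, events: list[ActivityEvent],
                channel: EmgChannel, params: DetectionParams
                ) -> tuple[bool, float | None]:
    """Apply the >= 50% rule to one 30 s epoch.

    Returns the tonic flag and, when tonic, the elevated baseline: the RMS
    of the raw signal over the increased-activity spans inside the epoch.
    """
    epoch_end = epoch_start + params.epoch_len
    spans = iv.clip([(ev.start, ev.end) for ev in events],
                    epoch_start, epoch_end)
    activity = iv.total(spans)
    tonic = activity >= params.tonic_fraction * params.epoch_len - _EPS
    if not tonic:
        return False, None
    return True, _signal_rms(channel, iv.merge(spans))


def rescore_phasic_in_tonic(channel: EmgChannel, epoch_start: float,
                            free_runs: np.ndarray, elevated_baseline: float,
                            params: DetectionParams) -> list[ActivityEvent]:
    """Re-run detection inside a tonic epoch against the elevated baseline.

    Only bouts at twice the background tonic level survive; the resulting
    events replace the epoch's phasic/intermediate events (the tonic flag
    itself is unchanged).
    """
    epoch_end = epoch_start + params.epoch_len
    events: list[ActivityEvent] = []
    for s, e in iv.clip(free_runs, epoch_start, epoch_end):
        events.extend(_events_in_run(channel, s, e,
                                     elevated_baseline, params))
    return events


@dataclass
class ScoreTable:
    """Per-channel tonic/phasic/any flags with validity.

    ``epochs``: one row per REM 30 s epoch (index = onset seconds) with
    ``valid`` (artefact-free), ``tonic`` and ``elevated_baseline_mv``.
    ``minis``: one row per 3 s mini-epoch with ``valid``, ``phasic``,
    ``any`` and the parent ``epoch_onset``.
    """

    epochs: pd.DataFrame
    minis: pd.DataFrame
    events: list[ActivityEvent] = field(default_factory=list)


def score_mini_epochs(epochs: pd.DataFrame, minis: pd.DataFrame,
                      events: list[ActivityEvent],
                      rescored: dict[float, list[ActivityEvent]],
                      params: DetectionParams) -> pd.DataFrame:
    """Fill phasic/any flags on valid mini-epochs.

    A valid mini-epoch is phasic iff it overlaps an event of duration up to
    5 s, and "any" iff it overlaps an event of duration up to 15 s or lies
    inside a tonic epoch.  Inside tonic epochs the post-rescoring events
    are used for phasic; events longer than 15 s outside tonic epochs
    contribute to neither category.
    """
    minis = minis.copy()
    minis["phasic"] = False
    minis["any"] = False
    tonic_onsets = set(epochs.index[epochs["tonic"]])
    for onset, row in minis.iterrows():
        if not row["valid"]:
            continue
        lo, hi = onset, onset + params.mini_epoch_len
        epoch_onset = row["epoch_onset"]
        in_tonic = epoch_onset in tonic_onsets
        pool = rescored.get(epoch_onset, []) if in_tonic else events
        phasic = any(ev.start < hi and ev.end > lo
                     and ev.duration <= params.phasic_max + _EPS
                     for ev in pool)
        any_flag = in_tonic or any(
            ev.start < hi and ev.end > lo
            and ev.duration <= params.intermediate_max + _EPS
            for ev in pool)
        minis.loc[onset, "phasic"] = phasic
        minis.loc[onset, "any"] = any_flag
    return minis


@dataclass
class ChannelScore:
    """Full scoring result for one EMG channel."""

    role: Role
    discarded: bool = False
    reason: str = ""
    baselines: BaselineAssignment | None = None
    table: ScoreTable | None = None
    events_raw: list[ActivityEvent] = field(default_factory=list)

    @property
    def events(self) -> list[ActivityEvent]:
        return self.table.events if self.table is not None else []


def _epoch_grid(hypnogram: Hypnogram, mask: ArtefactMask,
                params: DetectionParams
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    onsets = hypnogram.rem_epoch_onsets()
    epochs = pd.DataFrame(index=pd.Index(onsets, name="onset_s"))
    epochs["valid"] = [mask.is_clean(t, t + params.epoch_len) for t in onsets]
    epochs["tonic"] = False
    epochs["elevated_baseline_mv"] = np.nan
    rows = []
    for t in onsets:
        for k in range(params.minis_per_epoch):
            m = t + k * params.mini_epoch_len
            rows.append((m, t, mask.is_clean(m, m + params.mini_epoch_len)))
    minis = pd.DataFrame(rows, columns=["onset_s", "epoch_onset", "valid"])
    minis = minis.set_index("onset_s")
    return epochs, minis


def score_channel(channel: EmgChannel, hypnogram: Hypnogram,
                  segments: list[RemSegment], mask: ArtefactMask,
                  params: DetectionParams) -> ChannelScore:
    """Score one resampled channel: baseline, events, epoch/mini flags."""
    baselines = assign_baselines(channel, segments, mask, params)
    if not baselines.usable:
        return ChannelScore(role=channel.role, discarded=True,
                            reason="no measurable baseline in any REM period",
                            baselines=baselines)

    events: list[ActivityEvent] = []
    free_by_segment: dict[int, np.ndarray] = {}
    for i, seg in enumerate(segments):
        runs = mask.free_runs(seg)
        free_by_segment[i] = runs
        baseline = baselines.amplitudes[i]
        for s, e in runs:
            events.extend(_events_in_run(channel, s, e, baseline, params))

    epochs, minis = _epoch_grid(hypnogram, mask, params)

    seg_of_epoch = {}
    for t in epochs.index:
        for i, seg in enumerate(segments):
            if seg.start - _EPS <= t and t + params.epoch_len <= seg.end + _EPS:
                seg_of_epoch[t] = i
                break

    rescored: dict[float, list[ActivityEvent]] = {}
    for t in epochs.index:
        if not epochs.loc[t, "valid"]:
            continue
        tonic, elevated = score_tonic(t, events, channel, params)
        epochs.loc[t, "tonic"] = tonic
        if tonic:
            epochs.loc[t, "elevated_baseline_mv"] = elevated
            runs = free_by_segment.get(seg_of_epoch.get(t, -1),
                                       np.empty((0, 2)))
            rescored[t] = rescore_phasic_in_tonic(channel, t, runs,
                                                  elevated, params)

    minis = score_mini_epochs(epochs, minis, events, rescored, params)
    final = _final_events(channel, epochs, events, rescored, params)
    table = ScoreTable(epochs=epochs, minis=minis, events=final)
    return ChannelScore(role=channel.role, baselines=baselines,
                        table=table, events_raw=events)


def _final_events(channel: EmgChannel, epochs: pd.DataFrame,
                  events: list[ActivityEvent],
                  rescored: dict[float, list[ActivityEvent]],
                  params: DetectionParams) -> list[ActivityEvent]:
    """Reported event list: originals outside tonic epochs, plus one tonic
    span and the surviving rescored events per tonic epoch."""
    tonic_spans = [(t, t + params.epoch_len)
                   for t in epochs.index[epochs["tonic"]]]
    out: list[ActivityEvent] = []
    for ev in events:
        if not any(ev.start < hi and ev.end > lo for lo, hi in tonic_spans):
            out.append(ev)
    for t in epochs.index[epochs["tonic"]]:
        lo, hi = t, t + params.epoch_len
        inside = iv.clip([(ev.start, ev.end) for ev in events], lo, hi)
        if len(inside):
            amp = max(ev.max_amplitude for ev in events
                      if ev.start < hi and ev.end > lo)
            out.append(ActivityEvent(
                channel=channel.role, start=float(inside[0, 0]),
                end=float(inside[-1, 1]), category=Category.TONIC,
                max_amplitude=amp))
        out.extend(rescored.get(t, []))
    return sorted(out, key=lambda e: e.start)


@dataclass
class RecordingScore:
    channels: dict[Role, ChannelScore]
    segments: list[RemSegment]
    masks: dict[Role, ArtefactMask]
    params: DetectionParams
    policy: str


class NoRemSleepError(RuntimeError):
    """The hypnogram contains no REM sleep; nothing can be scored."""


def score_recording(recording: RecordingSet, hypnogram: Hypnogram,
                    events: dict[EventKind, EventList] | None = None,
                    params: DetectionParams | None = None,
                    policy: str = "full",
                    apply_filter: bool = False) -> RecordingScore:
    """End-to-end scoring of every mapped channel of a recording.

    ``policy`` selects the artefact handling: ``"full"`` excludes arousal,
    respiratory and snore events (snore on the chin only) plus detected
    electrode detachment; ``"arousal-only"`` excludes scored arousals only.
    The pipeline is deterministic: identical inputs give identical scores.
    """
    params = params or DetectionParams()
    events = events or {}
    if policy not in ("full", "arousal-only"):
        raise ValueError(f"unknown artefact policy {policy!r}")
    segments = extract_rem_segments(hypnogram, params)
    if not segments:
        raise NoRemSleepError("no REM sleep in the hypnogram")

    if policy == "arousal-only":
        masked_events = {k: v for k, v in events.items()
                         if k is EventKind.AROUSAL}
    else:
        masked_events = dict(events)

    channels: dict[Role, ChannelScore] = {}
    masks: dict[Role, ArtefactMask] = {}
    for ch in recording.channels:
        ch = resample(ch, params.fs_target)
        if apply_filter:
            ch = bandlimit(ch, params.filter_hp, params.filter_lp,
                           params.filter_notch)
        if policy == "full":
            det = [detect_detachment(ch, seg, params) for seg in segments]
            det = np.vstack([d for d in det if len(d)]) \
                if any(len(d) for d in det) else None
        else:
            det = None
        mask = build_artefact_mask(segments, masked_events, det, ch.role)
        masks[ch.role] = mask
        channels[ch.role] = score_channel(ch, hypnogram, segments, mask,
                                          params)
    return RecordingScore(channels=channels, segments=segments, masks=masks,
                          params=params, policy=policy)
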