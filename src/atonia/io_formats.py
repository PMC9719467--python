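"""Reading polysomnography inputs and writing scorer outputs.

Inputs: an EDF/EDF+C recording (read through :mod:`mne`), a plain-text sleep
profile (one 30-s epoch per line), and plain-text event lists (arousal,
respiratory, snore).  The text formats vary between vendor systems, so both
are parsed through a small declarative :class:`TextDialect`; the shipped
default is a best-effort reconstruction of a common vendor export
(``HH:MM:SS,fff; STAGE``) and is documented as such.

Outputs: a CSV with exact event timestamps, a per-channel summary table and
a combined-channel summary table (CSV or XLSX).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd


class Role(str, Enum):
    """Electrode placement of an EMG channel."""

    MENTALIS = "mentalis"
    FDS_LEFT = "fds_left"
    FDS_RIGHT = "fds_right"
    TA_LEFT = "ta_left"
    TA_RIGHT = "ta_right"
    OTHER = "other"


#: Channels on which snore intervals are treated as artefacts.  Snoring
#: contaminates the chin electrode only; limb channels keep those spans.
SNORE_SENSITIVE = frozenset({Role.MENTALIS})


class Stage(str, Enum):
    WAKE = "W"
    N1 = "N1"
    N2 = "N2"
    N3 = "N3"
    REM = "REM"
    UNSCORED = "unscored"


class EventKind(str, Enum):
    AROUSAL = "arousal"
    RESPIRATORY = "respiratory"
    SNORE = "snore"


class UnsupportedFormatError(ValueError):
    """The file is not a supported (continuous) EDF recording."""


class MissingChannelError(KeyError):
    """A channel named in the channel map is absent from the recording."""


class ProfileParseError(ValueError):
    """A text line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class EmptyHypnogramError(ValueError):
    """The sleep profile contains no epochs."""


@dataclass
class EmgChannel:
    """One EMG signal: placement role, samples in mV, sampling rate in Hz."""

    role: Role
    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"channel {self.label or self.role}: "
                             "samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class RecordingSet:
    channels: list[EmgChannel]
    recording_start: _dt.datetime
    duration: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("recording duration must be positive")
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")

    def channel(self, role: Role) -> EmgChannel:
        for c in self.channels:
            if c.role == role:
                return c
        raise MissingChannelError(role)

    @property
    def roles(self) -> list[Role]:
        return [c.role for c in self.channels]


@dataclass
class Hypnogram:
    """30-s sleep-stage epochs, times in seconds from recording start."""

    onsets: np.ndarray                 # epoch start times, seconds
    stages: list[Stage]
    epoch_len: float = 30.0

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        if len(self.onsets) != len(self.stages):
            raise ValueError("onsets and stages differ in length")
        if len(self.onsets) == 0:
            raise EmptyHypnogramError("hypnogram has no epochs")
        if np.any(np.diff(self.onsets) < self.epoch_len - 1e-9):
            raise ValueError("epochs overlap")

    def __len__(self) -> int:
        return len(self.stages)

    def __eq__(self, other) -> bool:
        return (isinstance(other, Hypnogram)
                and self.epoch_len == other.epoch_len
                and self.stages == other.stages
                and np.allclose(self.onsets, other.onsets, atol=1e-6))

    def rem_epoch_onsets(self) -> np.ndarray:
        return self.onsets[[s is Stage.REM for s in self.stages]]


@dataclass
class EventList:
    kind: EventKind
    intervals: np.ndarray              # (n, 2) start/end seconds, sorted

    def __post_init__(self):
        a = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if np.any(a[:, 1] <= a[:, 0]):
            raise ValueError("event end must follow event start")
        self.intervals = a[np.argsort(a[:, 0])] if len(a) else a

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# text dialects

_DEFAULT_STAGES = {
    "w": Stage.WAKE, "wake": Stage.WAKE, "wk": Stage.WAKE,
    "n1": Stage.N1, "s1": Stage.N1, "1": Stage.N1,
    "n2": Stage.N2, "s2": Stage.N2, "2": Stage.N2,
    "n3": Stage.N3, "s3": Stage.N3, "3": Stage.N3, "n4": Stage.N3,
    "rem": Stage.REM, "r": Stage.REM,
    "artefact": Stage.UNSCORED, "artifact": Stage.UNSCORED,
    "a": Stage.UNSCORED, "movement": Stage.UNSCORED, "?": Stage.UNSCORED,
    "unscored": Stage.UNSCORED,
}


@dataclass
class TextDialect:
    """Grammar of the plain-text sleep-profile and event exports.

    ``timestamp_format`` is a ``strptime`` pattern for clock times; ``None``
    means timestamps are plain seconds from recording start.  Stage tokens
    are matched case-insensitively against ``stage_names``; unknown tokens
    map to ``unscored``.
    """

    timestamp_format: str | None = "%H:%M:%S,%f"
    separator: str = ";"
    stage_names: dict[str, Stage] = field(
        default_factory=lambda: dict(_DEFAULT_STAGES))

    def parse_time(self, token: str, recording_start: _dt.datetime | None,
                   line_number: int) -> float:
        token = token.strip()
        if self.timestamp_format is None:
            try:
                return float(token)
            except ValueError:
                raise ProfileParseError(
                    f"cannot parse {token!r} as seconds", line_number)
        try:
            t = _dt.datetime.strptime(token, self.timestamp_format)
        except ValueError:
            raise ProfileParseError(
                f"cannot parse timestamp {token!r} with format "
                f"{self.timestamp_format!r}", line_number)
        if recording_start is None:
            raise ValueError(
                "clock-time dialect needs recording_start to anchor times")
        clock = _dt.timedelta(hours=t.hour, minutes=t.minute,
                              seconds=t.second, microseconds=t.microsecond)
        start = _dt.timedelta(hours=recording_start.hour,
                              minutes=recording_start.minute,
                              seconds=recording_start.second,
                              microseconds=recording_start.microsecond)
        rel = (clock - start).total_seconds()
        if rel < 0:                       # crossed midnight
            rel += 86400.0
        return rel

    def format_time(self, seconds: float,
                    recording_start: _dt.datetime | None) -> str:
        if self.timestamp_format is None:
            return f"{seconds:.3f}"
        if recording_start is None:
            raise ValueError("clock-time dialect needs recording_start")
        t = recording_start + _dt.timedelta(seconds=round(seconds * 1e3) / 1e3)
        out = t.strftime(self.timestamp_format)
        if "%f" in self.timestamp_format:  # millisecond precision
            out = out[:-3]
        return out

    def stage_for(self, token: str) -> Stage:
        return self.stage_names.get(token.strip().lower(), Stage.UNSCORED)


DEFAULT_DIALECT = TextDialect()


def _content_lines(path) -> list[tuple[int, str]]:
    lines = Path(path).read_text().splitlines()
    return [(i + 1, ln) for i, ln in enumerate(lines)
            if ln.strip() and not ln.lstrip().startswith("#")]


def parse_sleep_profile(path, dialect: TextDialect = DEFAULT_DIALECT,
                        recording_start: _dt.datetime | None = None,
                        epoch_len: float = 30.0) -> Hypnogram:
    """Parse a plain-text hypnogram: one ``timestamp; stage`` line per epoch."""
    onsets, stages = [], []
    for ln, text in _content_lines(path):
        parts = text.split(dialect.separator)
        if len(parts) < 2:
            raise ProfileParseError(
                f"expected 'timestamp{dialect.separator} stage', got "
                f"{text!r}", ln)
        onsets.append(dialect.parse_time(parts[0], recording_start, ln))
        stages.append(dialect.stage_for(parts[1]))
    if not onsets:
        raise EmptyHypnogramError(f"{path}: no epochs found")
    return Hypnogram(onsets=np.array(onsets), stages=stages,
                     epoch_len=epoch_len)


def serialize_sleep_profile(hypnogram: Hypnogram, path,
                            dialect: TextDialect = DEFAULT_DIALECT,
                            recording_start: _dt.datetime | None = None) -> None:
    stage_token = {Stage.WAKE: "Wake", Stage.N1: "N1", Stage.N2: "N2",
                   Stage.N3: "N3", Stage.REM: "REM",
                   Stage.UNSCORED: "Unscored"}
    with open(path, "w") as fh:
        for onset, stage in zip(hypnogram.onsets, hypnogram.stages):
            ts = dialect.format_time(onset, recording_start)
            fh.write(f"{ts}{dialect.separator} {stage_token[stage]}\n")


def parse_events(path, kind: EventKind,
                 dialect: TextDialect = DEFAULT_DIALECT,
                 recording_start: _dt.datetime | None = None) -> EventList:
    """Parse an event list: ``start; end`` or ``start; duration_s`` per line.

    The second field is read as an end timestamp when it matches the
    dialect's timestamp format, else as a duration in seconds.  An empty
    file is a valid list with no events.
    """
    intervals = []
    for ln, text in _content_lines(path):
        parts = text.split(dialect.separator)
        if len(parts) < 2:
            raise ProfileParseError(
                f"expected 'start{dialect.separator} end-or-duration', got "
                f"{text!r}", ln)
        start = dialect.parse_time(parts[0], recording_start, ln)
        token = parts[1].strip()
        try:
            end = dialect.parse_time(token, recording_start, ln)
        except ProfileParseError:
            try:
                end = start + float(token)
            except ValueError:
                raise ProfileParseError(
                    f"cannot parse {token!r} as end time or duration", ln)
        if end <= start:
            raise ProfileParseError(
                f"non-positive event duration ({start} .. {end})", ln)
        intervals.append((start, end))
    return EventList(kind=kind, intervals=np.array(intervals).reshape(-1, 2))


def serialize_events(events: EventList, path,
                     dialect: TextDialect = DEFAULT_DIALECT,
                     recording_start: _dt.datetime | None = None) -> None:
    with open(path, "w") as fh:
        for s, e in events.intervals:
            fh.write(f"{dialect.format_time(s, recording_start)}"
                     f"{dialect.separator} "
                     f"{dialect.format_time(e, recording_start)}\n")


# ---------------------------------------------------------------------------
# EDF

_UNIT_TO_MV = {"mv": 1.0, "uv": 1e-3, "µv": 1e-3, "v": 1e3, "": 1.0}


def _edf_header_fields(path) -> tuple[str, _dt.datetime, float]:
    """Read (reserved-field, start datetime, duration s) from an EDF header."""
    with open(path, "rb") as fh:
        hdr = fh.read(256)
    if len(hdr) < 256:
        raise UnsupportedFormatError(f"{path}: truncated EDF header")
    reserved = hdr[192:236].decode("ascii", "replace").strip()
    date = hdr[168:176].decode("ascii", "replace").strip()
    time = hdr[176:184].decode("ascii", "replace").strip()
    n_rec = int(hdr[236:244].decode("ascii", "replace").strip() or "0")
    rec_dur = float(hdr[244:252].decode("ascii", "replace").strip() or "0")
    try:
        d, m, y = (int(v) for v in date.split("."))
        hh, mm, ss = (int(v) for v in time.split("."))
        y += 2000 if y < 85 else 1900          # EDF two-digit year pivot
        start = _dt.datetime(y, m, d, hh, mm, ss)
    except ValueError:
        raise UnsupportedFormatError(f"{path}: unparseable EDF start time")
    return reserved, start, n_rec * rec_dur


def read_recording(path, channel_map: dict[str, Role | str]) -> RecordingSet:
    """Read the mapped EMG channels of an EDF/EDF+C file, in mV.

    ``channel_map`` maps raw EDF labels to roles; unmapped channels are
    dropped.  Discontinuous (EDF+D) files are rejected.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    reserved, start, duration = _edf_header_fields(path)
    if reserved.upper().startswith("EDF+D"):
        raise UnsupportedFormatError(
            f"{path}: discontinuous EDF+D recordings are not supported")
    channel_map = {k: Role(v) for k, v in channel_map.items()}
    raw = mne.io.read_raw_edf(str(path), include=list(channel_map),
                              preload=True, verbose="error")
    missing = set(channel_map) - set(raw.ch_names)
    if missing:
        raise MissingChannelError(
            f"channels {sorted(missing)} not in {path.name}; "
            f"available: {raw.ch_names}")
    data = raw.get_data() * 1e3            # mne returns SI volts -> mV
    channels = [
        EmgChannel(role=channel_map[name], samples=data[i],
                   fs=float(raw.info["sfreq"]), label=name)
        for i, name in enumerate(raw.ch_names)
    ]
    if duration <= 0:
        duration = channels[0].duration if channels else 0.0
    return RecordingSet(channels=channels, recording_start=start,
                        duration=duration)


# ---------------------------------------------------------------------------
# outputs

EVENT_COLUMNS = ["channel", "category", "start_s", "end_s",
                 "duration_s", "max_amplitude_mv"]


def events_frame(events_by_channel: dict[Role, list]) -> pd.DataFrame:
    """Flatten per-channel activity events into the output event table."""
    rows = []
    for role, events in events_by_channel.items():
        for ev in events:
            rows.append({
                "channel": role.value,
                "category": ev.category.value,
                "start_s": round(ev.start, 3),
                "end_s": round(ev.end, 3),
                "duration_s": round(ev.end - ev.start, 3),
                "max_amplitude_mv": ev.max_amplitude,
            })
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return df.sort_values(["channel", "start_s"]).reset_index(drop=True)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"channel": str, "category": str})


def _write_table(df: pd.DataFrame, path: Path, fmt: str) -> Path:
    if fmt == "xlsx":
        path = path.with_suffix(".xlsx")
        df.to_excel(path, index=False)
    else:
        path = path.with_suffix(".csv")
        df.to_csv(path, index=False)
    return path


def write_outputs(out_dir, events_by_channel: dict[Role, list],
                  channel_summaries: pd.DataFrame,
                  combined_summaries: pd.DataFrame,
                  fmt: str = "csv") -> dict[str, Path]:
    """Write the three scorer outputs.

    1. ``events.csv`` -- exact event timestamps (millisecond precision);
    2. ``channel_summary`` -- tonic/phasic/any counts and percentages plus
       bout statistics per channel;
    3. ``combined_summary`` -- combined-channel percentages.
    """
    if fmt not in ("csv", "xlsx"):
        raise ValueError(f"unsupported summary format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    ev = events_frame(events_by_channel)
    paths["events"] = out_dir / "events.csv"
    ev.to_csv(paths["events"], index=False)
    paths["channel_summary"] = _write_table(
        channel_summaries, out_dir / "channel_summary", fmt)
    paths["combined_summary"] = _write_table(
        combined_summaries, out_dir / "combined_summary", fmt)
    return paths
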