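"""Detection parameters, resampling, and optional band filtering.

The scorer works on a fixed 256 Hz grid.  Recordings at other rates are
brought onto it by cubic-spline interpolation (the spline passes through the
original sample points).  Band filtering (10-100 Hz band-pass plus 50 Hz
notch) mirrors the filters typically applied at recording time; it is OFF by
default because clinical exports usually arrive pre-filtered, and can be
enabled for raw inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, fields

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, iirnotch, sosfiltfilt, filtfilt

from .io_formats import EmgChannel


class ParameterError(ValueError):
    """A detection parameter violates the scorer's invariants."""


@dataclass(frozen=True)
class DetectionParams:
    """Every numeric constant of the SINBAR scoring algorithm.

    Amplitudes are in mV, durations in seconds, rates in Hz.  The defaults
    are the published rule set: activity is any 30 ms RMS window exceeding
    twice the per-period baseline amplitude, events must last more than
    0.1 s and end at sub-threshold interruptions of at least 0.25 s, phasic
    events last up to 5 s, intermediate up to 15 s, and a 30 s epoch is
    tonic when at least half of it is covered by increased activity.
    """

    fs_target: float = 256.0          # working sampling rate
    rms_window: float = 0.030         # RMS sliding-window length
    rms_step: float = 0.015           # RMS window step = temporal resolution
    threshold_factor: float = 2.0     # activity threshold, x baseline
    min_bout: float = 0.1             # minimum seed-run duration (strict >)
    max_gap: float = 0.25             # interruption that ends an event (>=)
    phasic_max: float = 5.0           # phasic iff duration <= phasic_max
    intermediate_max: float = 15.0    # intermediate iff phasic_max < d <= this
    tonic_fraction: float = 0.5       # tonic iff activity >= fraction * epoch
    epoch_len: float = 30.0           # sleep-stage epoch length
    mini_epoch_len: float = 3.0       # phasic/any scoring unit
    min_rem_period: float = 150.0     # REM period vs. bout boundary
    detachment_rms: float = 0.05      # mV; below = electrode detachment
    baseline_window: float = 30.0     # baseline rolling-window length
    baseline_window_fallback: float = 15.0
    filter_hp: float = 10.0
    filter_lp: float = 100.0
    filter_notch: float | None = 50.0

    def __post_init__(self) -> None:
        durs = (self.rms_window, self.rms_step, self.min_bout, self.max_gap,
                self.phasic_max, self.intermediate_max, self.epoch_len,
                self.mini_epoch_len, self.min_rem_period,
                self.baseline_window, self.baseline_window_fallback)
        if any(d <= 0 for d in durs) or self.fs_target <= 0:
            raise ParameterError("all durations and rates must be positive")
        if self.rms_step > self.rms_window:
            raise ParameterError("rms_step must not exceed rms_window")
        if not (self.min_bout < self.phasic_max
                < self.intermediate_max < self.epoch_len):
            raise ParameterError(
                "need min_bout < phasic_max < intermediate_max < epoch_len")
        n = self.epoch_len / self.mini_epoch_len
        if abs(n - round(n)) > 1e-9:
            raise ParameterError("mini_epoch_len must divide epoch_len")
        if self.threshold_factor <= 1:
            raise ParameterError("threshold_factor must exceed 1")

    @property
    def minis_per_epoch(self) -> int:
        return round(self.epoch_len / self.mini_epoch_len)

    def with_overrides(self, **kw) -> "DetectionParams":
        return replace(self, **kw)

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


class DegenerateInputError(ValueError):
    """Input too short for the requested operation."""


def resample(channel: EmgChannel, fs_target: float) -> EmgChannel:
    """Resample onto the target rate with a cubic spline.

    At equal rates the channel is returned unchanged.  The spline
    interpolates through the original sample instants, so values at shared
    time points are preserved.
    """
    if channel.fs == fs_target:
        return channel
    n = len(channel.samples)
    if n < 4:
        raise DegenerateInputError(
            f"cubic-spline resampling needs >= 4 samples, got {n}")
    t_old = np.arange(n) / channel.fs
    duration = n / channel.fs
    n_new = int(round(duration * fs_target))
    t_new = np.arange(n_new) / fs_target
    spline = CubicSpline(t_old, channel.samples)
    new = spline(np.clip(t_new, 0.0, t_old[-1]))
    return EmgChannel(role=channel.role, samples=new, fs=fs_target,
                      label=channel.label)


def bandlimit(channel: EmgChannel, hp: float, lp: float,
              notch: float | None = None) -> EmgChannel:
    """Zero-phase band-pass (4th-order Butterworth) plus optional notch.

    Zero-phase (forward-backward) filtering avoids shifting burst onsets.
    """
    nyq = channel.fs / 2.0
    if not (0 < hp < lp):
        raise ParameterError("need 0 < hp < lp")
    if lp >= nyq:
        raise ParameterError(f"low-pass {lp} Hz >= Nyquist {nyq} Hz")
    sos = butter(4, [hp, lp], btype="band", fs=channel.fs, output="sos")
    x = sosfiltfilt(sos, channel.samples)
    if notch is not None:
        b, a = iirnotch(notch, Q=30.0, fs=channel.fs)
        x = filtfilt(b, a, x)
    return EmgChannel(role=channel.role, samples=x, fs=channel.fs,
                      label=channel.label)
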