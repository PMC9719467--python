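"""Minimal EDF (16-bit, continuous) writer for the synthetic fixtures.

Writes plain EDF with one-second data records and a symmetric physical
range per signal, chosen from the signal's own extremes so the 16-bit
quantisation step stays far below the EMG baseline amplitude.  Intended for
fixture generation only; reading goes through mne.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np


def _field(value, width: int) -> bytes:
    b = str(value).encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field {value!r} exceeds {width} bytes")
    return b.ljust(width)


def _num(value: float, width: int = 8) -> str:
    for fmt in (f"{{:.{p}g}}" for p in (7, 6, 5, 4)):
        s = fmt.format(value)
        if len(s) <= width:
            return s
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf(path, signals: list[np.ndarray], labels: list[str],
              fs: int, start: _dt.datetime, physical_dim: str = "mV",
              patient: str = "X X X X",
              recording: str = "Startdate X X X X") -> None:
    """Write equally sampled signals (in `physical_dim` units) as EDF.

    Signals shorter than a whole number of 1-s records are zero-padded at
    the end.  The digital range is the full int16 span; the physical range
    is +/- max|signal| per channel, so the round-trip error is at most half
    a quantisation step.
    """
    if int(fs) != fs or fs <= 0:
        raise ValueError("fs must be a positive integer for 1 s records")
    fs = int(fs)
    if len(signals) != len(labels):
        raise ValueError("one label per signal required")
    ns = len(signals)
    n_max = max(len(s) for s in signals)
    n_rec = int(np.ceil(n_max / fs))
    pmax = [max(1e-6, float(np.max(np.abs(np.asarray(s, dtype=float)))))
            for s in signals]

    header = b"".join([
        _field("0", 8),
        _field(patient, 80),
        _field(recording, 80),
        _field(start.strftime("%d.%m.%y"), 8),
        _field(start.strftime("%H.%M.%S"), 8),
        _field(256 * (1 + ns), 8),
        _field("", 44),                      # reserved; blank = continuous
        _field(n_rec, 8),
        _field(1, 8),                        # record duration, seconds
        _field(ns, 4),
    ])
    per_signal = [
        (labels, 16),
        (["" for _ in signals], 80),                       # transducer
        ([physical_dim] * ns, 8),
        ([_num(-p) for p in pmax], 8),                     # physical min
        ([_num(p) for p in pmax], 8),                      # physical max
        (["-32768"] * ns, 8),
        (["32767"] * ns, 8),
        (["" for _ in signals], 80),                       # prefiltering
        ([str(fs)] * ns, 8),
        (["" for _ in signals], 32),
    ]
    for values, width in per_signal:
        header += b"".join(_field(v, width) for v in values)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for sig, p in zip(signals, pmax):
                seg = np.zeros(fs)
                chunk = np.asarray(sig[r * fs:(r + 1) * fs], dtype=float)
                seg[:len(chunk)] = chunk
                # inverse of the EDF affine digital->physical mapping
                dig = np.round((seg + p) / (2 * p) * 65535.0) - 32768.0
                fh.write(np.clip(dig, -32768, 32767)
                         .astype("<i2").tobytes())


def quantisation_step(signal: np.ndarray) -> float:
    """The physical value of one digital unit for `signal` as written."""
    p = max(1e-6, float(np.max(np.abs(signal))))
    return 2 * p / 65535.0
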