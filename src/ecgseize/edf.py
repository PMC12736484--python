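"""Minimal single-channel EDF writer.

Covers exactly what the synthetic cohort needs: one ECG channel, int16
samples, physical units in millivolt.  Reading goes through ``mne`` (see
``ecgseize.io``), which independently validates the files this writer
produces.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        b = b[:width]
    return b.ljust(width)


def _fit8(value: float, direction: str) -> str:
    """Render ``value`` in <= 8 ASCII chars, rounded outward so the printed
    physical range still covers the data."""
    for digits in (6, 5, 4, 3, 2, 1):
        s = f"{value:.{digits}g}"
        if len(s) <= 8:
            v = float(s)
            if direction == "floor" and v > value:
                v -= abs(v) * 10.0 ** (-digits) + 10.0**-digits
                s = f"{v:.{digits}g}"
            elif direction == "ceil" and v < value:
                v += abs(v) * 10.0 ** (-digits) + 10.0**-digits
                s = f"{v:.{digits}g}"
            if len(s) <= 8:
                return s
    return f"{value:.0f}"[:8]


def write_edf(
    path,
    signal: np.ndarray,
    fs: float,
    label: str = "ECG",
    physical_dimension: str = "mV",
) -> None:
    """Write ``signal`` (mV) as a one-channel EDF file at ``fs`` Hz.

    Uses one-second data records when the signal length divides evenly,
    falling back to one-sample records otherwise so the sample count always
    round-trips exactly.
    """
    sig = np.asarray(signal, dtype=float)
    if sig.ndim != 1 or len(sig) == 0:
        raise ValueError("signal must be a nonempty 1-D array")
    n = len(sig)
    spr = int(round(fs))
    if spr > 0 and abs(fs - spr) < 1e-9 and n % spr == 0:
        record_duration = 1.0
    else:
        spr = 1
        record_duration = 1.0 / fs
    n_records = n // spr

    pmin = float(np.min(sig))
    pmax = float(np.max(sig))
    if pmax - pmin < 1e-12:  # constant signal: open a token range
        pmax = pmin + 1.0
    # Header fields are 8 ASCII chars; use the printable values for scaling
    # so the written samples stay consistent with the header.
    pmin_str = _fit8(pmin, "floor")
    pmax_str = _fit8(pmax, "ceil")
    pmin, pmax = float(pmin_str), float(pmax_str)
    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.round((sig - pmin) * scale + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad("01.01.20", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * 2), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad(f"{record_duration:g}", 8),
            _pad("1", 4),
        ]
    )
    sig_header = b"".join(
        [
            _pad(label, 16),
            _pad("", 80),
            _pad(physical_dimension, 8),
            _pad(pmin_str, 8),
            _pad(pmax_str, 8),
            _pad(str(_DIG_MIN), 8),
            _pad(str(_DIG_MAX), 8),
            _pad("", 80),
            _pad(str(spr), 8),
            _pad("", 32),
        ]
    )
    with open(Path(path), "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(digital[: n_records * spr].tobytes())
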