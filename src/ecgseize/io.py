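"""Recording input, quality control and preprocessing.

Quality control mirrors the benchmark's dataset handling: recordings
without an ECG channel are excluded, and so are recordings in which at
least 10% of the samples sit on an amplitude rail (electrode saturation).
Preprocessing band-passes 0.5-40 Hz with a zero-phase order-4 Butterworth
filter and decimates 256 Hz -> 8 Hz with anti-alias protection, so the
detectors operate on sub-4 Hz envelope and rhythm content.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import PreprocessedSeries, QCReport, Recording, SeizureAnnotation

SATURATION_EXCLUSION_THRESHOLD = 0.10  # "at least 10%" -> >= comparison
RAIL_PLATEAU_FRACTION = 0.005  # min fraction at an extremum to call it a rail


class NoECGChannelError(ValueError):
    """The file contains no resolvable ECG channel."""


class AnnotationParseError(ValueError):
    """Malformed annotation rows; carries the offending line numbers."""

    def __init__(self, message: str, lines: list[int]):
        super().__init__(message)
        self.lines = lines


def read_annotations(path) -> dict[str, list[SeizureAnnotation]]:
    """Read a TSV of (recording_id, onset_s, offset_s, seizure_type).

    Raises :class:`AnnotationParseError` listing every malformed row.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"recording_id", "onset_s", "offset_s", "seizure_type"}
    if not required.issubset(df.columns):
        raise AnnotationParseError(
            f"annotation file missing columns {sorted(required - set(df.columns))}",
            [],
        )
    out: dict[str, list[SeizureAnnotation]] = {}
    bad: list[int] = []
    for i, row in df.iterrows():
        try:
            onset = float(row["onset_s"])
            offset = float(row["offset_s"])
            ann = SeizureAnnotation(onset, offset, str(row["seizure_type"]))
        except (TypeError, ValueError):
            bad.append(int(i) + 2)  # 1-based line number incl. header
            continue
        out.setdefault(str(row["recording_id"]), []).append(ann)
    if bad:
        raise AnnotationParseError(
            f"malformed annotation rows at lines {bad}", bad
        )
    for anns in out.values():
        anns.sort(key=lambda a: a.onset)
    return out


def _read_edf_ecg(path) -> tuple[np.ndarray, float]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    ecg_names = [n for n in raw.ch_names if "ecg" in n.lower()]
    if not ecg_names:
        raise NoECGChannelError(f"no ECG channel in {path}")
    if len(ecg_names) > 1:
        raise ValueError(f"multiple ECG channels in {path}: {ecg_names}")
    data = raw.get_data(picks=[ecg_names[0]])[0]
    # mne scales EDF physical dimensions to SI units; our channels are mV
    return data * 1e3, float(raw.info["sfreq"])


def read_recording(
    path,
    annotation_path=None,
    patient_id: str | None = None,
    recording_id: str | None = None,
) -> Recording:
    """Read an EDF (one ECG channel) or two-column CSV recording.

    Annotations for the recording id are attached when ``annotation_path``
    is given.  A missing ECG channel raises :class:`NoECGChannelError`,
    which :func:`qc_recording` turns into a ``no_ecg`` exclusion.
    """
    path = Path(path)
    recording_id = recording_id or path.stem
    patient_id = patient_id or recording_id.split("_")[0]
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(dtype=float)
        sig = df["amplitude_mV"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError("CSV signal too short to infer sampling rate")
        fs = 1.0 / float(np.median(np.diff(t)))
    else:
        sig, fs = _read_edf_ecg(path)
    annotations: list[SeizureAnnotation] = []
    if annotation_path is not None:
        annotations = read_annotations(annotation_path).get(recording_id, [])
    return Recording(
        patient_id=patient_id,
        recording_id=recording_id,
        signal=sig,
        sampling_rate=fs,
        annotations=annotations,
    )


def detect_saturation(
    signal: np.ndarray, rails: tuple[float, float] | None = None
) -> float:
    """Fraction of samples sitting on an amplitude rail.

    Rails default to the signal's min/max when at least
    ``RAIL_PLATEAU_FRACTION`` of samples lie exactly there (plateau
    heuristic); otherwise the extrema are treated as ordinary samples and
    the fraction is 0.  With explicit ``rails`` every sample at or beyond
    either rail counts.
    """
    sig = np.asarray(signal, dtype=float)
    if len(sig) == 0:
        raise ValueError("empty signal")
    n = len(sig)
    if rails is not None:
        lo, hi = min(rails), max(rails)
        return float(np.count_nonzero((sig <= lo) | (sig >= hi))) / n
    frac = 0.0
    tol = 1e-12
    lo, hi = float(np.min(sig)), float(np.max(sig))
    candidates = {lo, hi}  # identical for a constant signal
    for rail in candidates:
        at = float(np.count_nonzero(np.abs(sig - rail) <= tol)) / n
        if at >= RAIL_PLATEAU_FRACTION:
            frac += at
    return min(frac, 1.0)


def qc_recording(
    recording: Recording | None,
    recording_id: str | None = None,
    saturation_threshold: float = SATURATION_EXCLUSION_THRESHOLD,
) -> QCReport:
    """QC verdict: ``no_ecg`` when the recording could not be read as ECG,
    ``saturated`` when the rail fraction reaches the exclusion threshold."""
    if recording is None:
        return QCReport(
            recording_id=recording_id or "unknown",
            has_ecg=False,
            saturation_fraction=0.0,
            excluded=True,
            exclusion_reason="no_ecg",
        )
    frac = detect_saturation(recording.signal)
    excluded = frac >= saturation_threshold
    return QCReport(
        recording_id=recording.recording_id,
        has_ecg=True,
        saturation_fraction=frac,
        excluded=excluded,
        exclusion_reason="saturated" if excluded else "none",
    )


def bandpass(
    signal: np.ndarray,
    fs: float,
    low_hz: float = 0.5,
    high_hz: float = 40.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    if fs <= 2 * high_hz:
        raise ValueError(
            f"sampling rate {fs} Hz cannot support a {high_hz} Hz cutoff"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float))


def preprocess(
    signal: np.ndarray,
    fs_in: float,
    fs_out: float = 8.0,
    low_hz: float = 0.5,
    high_hz: float = 40.0,
    order: int = 4,
    source_recording: str = "",
) -> PreprocessedSeries:
    """Band-pass then decimate to ``fs_out`` with anti-alias protection.

    Output length is ``floor(N * fs_out / fs_in)``; boundary samples are
    dropped, never padded.  Rates that cannot carry the band-pass
    (``fs_in <= 2 * high_hz``) are rejected rather than silently
    re-filtered, so an already-8 Hz series cannot pass through twice.
    """
    sig = np.asarray(signal, dtype=float)
    if fs_in <= 2 * high_hz:
        raise ValueError(
            f"fs_in={fs_in} Hz too low to band-pass at {high_hz} Hz"
        )
    factor = fs_in / fs_out
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("fs_out must divide fs_in")
    factor = int(round(factor))
    filtered = bandpass(sig, fs_in, low_hz, high_hz, order)
    down = sps.resample_poly(filtered, up=1, down=factor)
    n_out = int(math.floor(len(sig) * fs_out / fs_in))
    return PreprocessedSeries(
        samples=down[:n_out],
        sampling_rate=fs_out,
        source_recording=source_recording,
        filter_params=(low_hz, high_hz, order),
    )


def qc_table(reports: list[QCReport]) -> pd.DataFrame:
    """QC reports as a table (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "recording_id": r.recording_id,
                "has_ecg": r.has_ecg,
                "saturation_fraction": r.saturation_fraction,
                "excluded": r.excluded,
                "exclusion_reason": r.exclusion_reason,
            }
            for r in reports
        ]
    )
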