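"""Benchmark evaluation: event matching, metrics, responder stratification.

A detection credits a seizure when its interval overlaps the seizure's
target window.  Under strict matching the window is the annotated ictal
interval ``[onset, offset)``; under SDW (seizure detection window) matching
it is the union of that interval with ``[onset - 5 min, onset + 3 min)``,
capturing pre-ictal autonomic build-up and post-onset persistence.  Per
patient we report sensitivity (%), false-alarm rate (alarms/h outside every
target window) and the composite ``HMS = sensitivity - 0.4 * FAR``.

Responders are patients whose first seizure shows a heart-rate excursion
above 50 BPM within a 100-RR-interval window; heart rate comes from R-peaks
found with the two-moving-average (Elgendi) QRS detector on the raw 256 Hz
trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .core import (
    BootstrapCI,
    MatchingMode,
    McNemarResult,
    PatientMetrics,
    Recording,
    ResponderStatus,
    SeizureAnnotation,
    hms,
)

RESPONDER_HR_THRESHOLD = 50.0  # BPM
RESPONDER_RR_WINDOW = 100  # RR intervals


def seizure_window(
    seizure: SeizureAnnotation, mode: MatchingMode
) -> tuple[float, float]:
    """Target window for one seizure under the given matching mode.

    SDW windows are anchored on onset (-sdw_pre / +sdw_post) and unioned
    with the ictal interval so late-ictal detections still count.
    """
    if mode.mode == "strict":
        return (seizure.onset, seizure.offset)
    return (
        seizure.onset - mode.sdw_pre,
        max(seizure.onset + mode.sdw_post, seizure.offset),
    )


def _overlaps(det: tuple[float, float], win: tuple[float, float]) -> bool:
    start, end = det
    w0, w1 = win
    if end <= start:  # zero-length detections are points
        return w0 <= start < w1
    return start < w1 and w0 < end


@dataclass
class MatchResult:
    """Outcome of matching one recording's detections against its seizures."""

    detected: list[bool]  # per seizure, annotation order
    tp: int
    fn: int
    fp: int
    fp_detections: list[tuple[float, float]]


def match_events(
    detections,
    seizures: list[SeizureAnnotation],
    mode: MatchingMode | str = "strict",
) -> MatchResult:
    """Match detection intervals against seizure target windows.

    ``detections`` is a list of ``(start_s, end_s)`` pairs (half-open; a
    pair with ``end <= start`` is treated as a point).  A detection
    overlapping several windows credits each; detections overlapping no
    window are false positives.  Multiple detections on one seizure count
    it once.
    """
    if isinstance(mode, str):
        mode = MatchingMode(mode=mode)
    dets = sorted((float(a), float(b)) for a, b in detections)
    seiz = sorted(seizures, key=lambda s: s.onset)
    windows = [seizure_window(s, mode) for s in seiz]
    detected = [False] * len(seiz)
    fp_detections = []
    for det in dets:
        hit = False
        for k, win in enumerate(windows):
            if _overlaps(det, win):
                detected[k] = True
                hit = True
        if not hit:
            fp_detections.append(det)
    tp = sum(detected)
    return MatchResult(
        detected=detected,
        tp=tp,
        fn=len(seiz) - tp,
        fp=len(fp_detections),
        fp_detections=fp_detections,
    )


def compute_metrics(
    match: MatchResult,
    recorded_hours: float,
    patient_id: str = "",
    mode: str = "strict",
) -> PatientMetrics:
    """Sensitivity / FAR / HMS for one patient.

    Patients without seizures get ``sensitivity=None`` (excluded from
    sensitivity means downstream) but still contribute false alarms.
    """
    if recorded_hours <= 0:
        raise ValueError("recorded_hours must be positive")
    n_seiz = match.tp + match.fn
    sens = 100.0 * match.tp / n_seiz if n_seiz > 0 else None
    return PatientMetrics(
        patient_id=patient_id,
        sensitivity=sens,
        far=match.fp / recorded_hours,
        n_seizures=n_seiz,
        recorded_hours=recorded_hours,
        mode=mode,
    )


def mcnemar(n10: int, n01: int) -> McNemarResult:
    """Yates-corrected McNemar test on discordant seizure detections.

    ``chi2 = (|n10 - n01| - 1)^2 / (n10 + n01)`` against a chi-square with
    one degree of freedom.  With no discordant pairs the comparison carries
    no evidence and is reported as chi2=0, p=1.
    """
    if n10 < 0 or n01 < 0:
        raise ValueError("discordant counts must be nonnegative")
    n = n10 + n01
    if n == 0:
        return McNemarResult(n10=0, n01=0, chi2=0.0, p=1.0)
    chi2 = (abs(n10 - n01) - 1) ** 2 / n
    p = float(stats.chi2.sf(chi2, df=1))
    return McNemarResult(n10=n10, n01=n01, chi2=float(chi2), p=p)


def mcnemar_from_outcomes(a_detected, b_detected) -> McNemarResult:
    """McNemar comparison from aligned per-seizure hit vectors."""
    a = np.asarray(a_detected, dtype=bool)
    b = np.asarray(b_detected, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("outcome vectors must align on the same seizures")
    return mcnemar(int(np.sum(a & ~b)), int(np.sum(~a & b)))


def detect_r_peaks(
    signal: np.ndarray,
    fs: float,
    qrs_band: tuple[float, float] = (8.0, 20.0),
    w_peak_s: float = 0.120,
    w_beat_s: float = 0.611,
    beta: float = 0.08,
) -> np.ndarray:
    """R-peak times (s) via the two-moving-average QRS enhancement method.

    Band-pass to the QRS band, rectify and square, then compare a short
    (QRS-scale) moving average against a long (beat-scale) one offset by a
    fraction of the mean energy; blocks where the short average wins and
    that last at least one QRS width yield one R-peak each (the energy
    argmax within the block).
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < int(fs):
        return np.empty(0)
    sos = sps.butter(3, qrs_band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    z = np.square(np.maximum(y, 0.0))
    w1 = max(1, int(round(w_peak_s * fs)))
    w2 = max(1, int(round(w_beat_s * fs)))
    kernel1 = np.ones(w1) / w1
    kernel2 = np.ones(w2) / w2
    ma_peak = np.convolve(z, kernel1, mode="same")
    ma_beat = np.convolve(z, kernel2, mode="same")
    thr = ma_beat + beta * float(np.mean(z))
    active = ma_peak > thr
    # contiguous active blocks of at least one QRS width -> one beat each
    padded = np.concatenate([[False], active, [False]])
    rises = np.flatnonzero(np.diff(padded.astype(int)) == 1)
    falls = np.flatnonzero(np.diff(padded.astype(int)) == -1)
    peaks = []
    for a, b in zip(rises, falls):
        if b - a >= w1:
            peaks.append(a + int(np.argmax(z[a:b])))
    return np.asarray(peaks, dtype=float) / fs


def rr_intervals(
    peak_times: np.ndarray, rr_range: tuple[float, float] = (0.24, 3.0)
) -> np.ndarray:
    """Successive R-peak differences, restricted to physiological values."""
    rr = np.diff(np.asarray(peak_times, dtype=float))
    return rr[(rr >= rr_range[0]) & (rr <= rr_range[1])]


def classify_responder(
    recording: Recording,
    first_seizure: SeizureAnnotation | None = None,
    extension_step_s: float = 15.0,
) -> ResponderStatus:
    """Responder classification from the first seizure's heart-rate swing.

    Instantaneous heart rate is ``60/RR``.  The analysis window starts at
    the seizure interval and grows symmetrically into pre- and post-ictal
    signal until it holds at least 100 RR intervals (or the recording is
    exhausted, in which case the available intervals are used and flagged).
    A patient responds when max(HR) - min(HR) exceeds 50 BPM.
    """
    if first_seizure is None:
        if not recording.annotations:
            raise ValueError("recording has no seizure annotations")
        first_seizure = recording.annotations[0]
    peaks = detect_r_peaks(recording.signal, recording.sampling_rate)
    duration = recording.duration
    w0, w1 = first_seizure.onset, first_seizure.offset
    extended = False
    while True:
        in_win = peaks[(peaks >= w0) & (peaks < w1)]
        rr = rr_intervals(in_win)
        if len(rr) >= RESPONDER_RR_WINDOW:
            break
        if w0 <= 0 and w1 >= duration:
            break
        w0 = max(0.0, w0 - extension_step_s)
        w1 = min(duration, w1 + extension_step_s)
        extended = True
    if len(rr) == 0:
        return ResponderStatus(
            patient_id=recording.patient_id,
            is_responder=False,
            max_hr_change=0.0,
            rr_count_used=0,
            window_extended=extended,
        )
    hr = 60.0 / rr
    change = float(np.max(hr) - np.min(hr))
    return ResponderStatus(
        patient_id=recording.patient_id,
        is_responder=change > RESPONDER_HR_THRESHOLD,
        max_hr_change=change,
        rr_count_used=int(len(rr)),
        window_extended=extended,
    )


def bootstrap_ci(
    per_patient: list[PatientMetrics],
    metric: str = "sensitivity",
    iterations: int = 1000,
    seed: int = 0,
) -> BootstrapCI:
    """Patient-level bootstrap 95% CI of the patient-wise mean metric.

    Patients whose metric is undefined (no seizures) are dropped before
    resampling.  Degenerate single-patient input yields a point interval.
    """
    if metric not in ("sensitivity", "far", "hms"):
        raise ValueError("metric must be sensitivity, far or hms")
    values = np.asarray(
        [getattr(pm, metric) for pm in per_patient if getattr(pm, metric) is not None],
        dtype=float,
    )
    if len(values) == 0:
        raise ValueError("no patients with a defined metric value")
    rng = np.random.default_rng(seed)
    if len(values) == 1:
        return BootstrapCI(metric, float(values[0]), float(values[0]), iterations, seed)
    means = np.empty(iterations)
    for it in range(iterations):
        sample = values[rng.integers(0, len(values), size=len(values))]
        means[it] = sample.mean()
    lo, hi = np.percentile(means, [2.5, 97.5])
    return BootstrapCI(metric, float(lo), float(hi), iterations, seed)


def seizure_type_sensitivity(
    detected_per_model: dict[str, list[bool]],
    type_labels: list[str],
    known_types: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-seizure-type sensitivity per model plus the cross-model mean.

    ``detected_per_model`` maps model name to a hit vector aligned with
    ``type_labels``.  Unknown labels are grouped under ``other``.  Types
    absent from the data are omitted.
    """
    models = sorted(detected_per_model)
    n = len(type_labels)
    for m in models:
        if len(detected_per_model[m]) != n:
            raise ValueError(f"hit vector for {m} does not align with labels")
    if known_types is not None:
        labels = [t if t in known_types else "other" for t in type_labels]
    else:
        labels = list(type_labels)
    rows = []
    for stype in sorted(set(labels)):
        idx = [i for i, t in enumerate(labels) if t == stype]
        row = {"seizure_type": stype, "n": len(idx)}
        sens = []
        for m in models:
            hits = [detected_per_model[m][i] for i in idx]
            s = 100.0 * sum(hits) / len(idx)
            row[m] = s
            sens.append(s)
        row["mean_sensitivity"] = float(np.mean(sens))
        rows.append(row)
    return pd.DataFrame(rows)


def usable_seizure_count(
    annotated: int, no_ecg_losses: int, saturation_losses: int
) -> int:
    """Exclusion bookkeeping: usable = annotated - no-ECG - saturation."""
    usable = annotated - no_ecg_losses - saturation_losses
    if usable < 0:
        raise ValueError("losses exceed annotated seizures")
    return usable


def exclusion_bookkeeping(
    seizure_table: pd.DataFrame, qc_reports
) -> dict:
    """Usable seizure/patient counts from a seizure table and QC verdicts.

    ``seizure_table`` needs columns recording_id and patient_id (one row
    per annotated seizure).  Seizures on recordings excluded for ``no_ecg``
    or ``saturated`` are counted as losses.
    """
    qc = {r.recording_id: r for r in qc_reports}
    unknown = set(seizure_table["recording_id"]) - set(qc)
    if unknown:
        raise ValueError(f"seizures reference unknown recordings: {sorted(unknown)}")
    reasons = seizure_table["recording_id"].map(
        lambda rid: qc[rid].exclusion_reason
    )
    annotated = len(seizure_table)
    no_ecg = int((reasons == "no_ecg").sum())
    saturated = int((reasons == "saturated").sum())
    usable_mask = reasons == "none"
    usable_patients = sorted(
        seizure_table.loc[usable_mask, "patient_id"].unique()
    )
    return {
        "annotated": annotated,
        "no_ecg_losses": no_ecg,
        "saturation_losses": saturated,
        "usable": usable_seizure_count(annotated, no_ecg, saturated),
        "usable_patients": usable_patients,
    }


def patient_mean(per_patient: list[PatientMetrics], metric: str) -> float:
    """Unweighted mean over patients with a defined metric value."""
    vals = [
        getattr(pm, metric)
        for pm in per_patient
        if getattr(pm, metric) is not None
    ]
    if not vals:
        raise ValueError(f"no patients with defined {metric}")
    return float(np.mean(vals))


__all__ = [
    "MatchResult",
    "match_events",
    "seizure_window",
    "compute_metrics",
    "mcnemar",
    "mcnemar_from_outcomes",
    "detect_r_peaks",
    "rr_intervals",
    "classify_responder",
    "bootstrap_ci",
    "seizure_type_sensitivity",
    "usable_seizure_count",
    "exclusion_bookkeeping",
    "patient_mean",
    "hms",
]
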