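"""Synthetic wearable-ECG cohort generator.

Produces single-lead ECG at 256 Hz built from a PQRST template train driven
by an RR tachogram: instantaneous heart rate follows a baseline profile with
Gaussian beat-to-beat variability, and injected seizures raise the rate by a
configurable excursion (ramp up, ictal plateau, exponential post-ictal
decay).  Responder patients receive excursions above the 50 BPM criterion,
non-responders below it.  Optional amplitude saturation emulates electrode
rail-clipping in contiguous runs.  Every output is deterministic given the
cohort seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SEIZURE_TYPES, Recording, SeizureAnnotation

# PQRST template: (offset from R in seconds, amplitude mV, gaussian sigma s)
_WAVES = (
    (-0.200, 0.15, 0.040),  # P
    (-0.035, -0.12, 0.012),  # Q
    (0.000, 1.00, 0.016),  # R
    (0.035, -0.22, 0.012),  # S
    (0.280, 0.32, 0.060),  # T
)

#: Test-set seizure-type frequencies used as the default sampling weights.
DEFAULT_TYPE_COUNTS = {
    "ua_nm": 4,
    "ia": 15,
    "f2b": 21,
    "a_um": 15,
    "a_nm": 15,
    "a_m_hyperkinetic": 12,
    "ia_m_automatisms": 16,
    "ia_m_hyperkinetic": 10,
    "ia_nm": 55,
}


def _default_type_distribution() -> dict[str, float]:
    total = sum(DEFAULT_TYPE_COUNTS.values())
    return {k: v / total for k, v in DEFAULT_TYPE_COUNTS.items()}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults describe the desk-scale benchmark cohort: ten patients, one
    six-minute recording each (one hour of signal in total), one seizure per
    recording, half the patients responders with a 70 BPM ictal excursion
    against 20 BPM for non-responders.
    """

    n_patients: int = 10
    recordings_per_patient: int = 1
    recording_duration: float = 360.0  # seconds
    seizures_per_recording: int = 1
    responder_fraction: float = 0.5
    baseline_hr: float = 70.0  # BPM
    hrv_sd: float = 3.0  # BPM beat-to-beat SD
    responder_hr_delta: float = 70.0  # BPM, must exceed 50
    nonresponder_hr_delta: float = 20.0  # BPM, must stay below 50
    seizure_duration_range: tuple[float, float] = (30.0, 60.0)
    seizure_type_distribution: dict[str, float] | None = None
    saturation_fraction: float = 0.0
    sampling_rate: float = 256.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.recordings_per_patient < 1:
            raise ValueError("cohort must contain at least one recording")
        if not self.responder_hr_delta > 50.0:
            raise ValueError("responder_hr_delta must exceed 50 BPM")
        if not self.nonresponder_hr_delta < 50.0:
            raise ValueError("nonresponder_hr_delta must stay below 50 BPM")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction outside [0, 1]")
        if not 0.0 <= self.saturation_fraction <= 1.0:
            raise ValueError("saturation_fraction outside [0, 1]")
        lo, hi = self.seizure_duration_range
        if not 0 < lo <= hi:
            raise ValueError("invalid seizure_duration_range")
        total_needed = self.seizures_per_recording * (hi + 120.0)
        if total_needed > self.recording_duration:
            raise ValueError(
                "recording too short for the requested seizures with context"
            )
        dist = self.type_distribution
        if abs(sum(dist.values()) - 1.0) > 1e-6:
            raise ValueError("seizure_type_distribution must sum to 1")
        unknown = set(dist) - set(SEIZURE_TYPES)
        if unknown:
            raise ValueError(f"unknown seizure types: {sorted(unknown)}")

    @property
    def type_distribution(self) -> dict[str, float]:
        return self.seizure_type_distribution or _default_type_distribution()


def _seizure_hr_bump(
    t: np.ndarray,
    onset: float,
    offset: float,
    hr_delta: float,
    ramp: float,
    decay_tau: float,
) -> np.ndarray:
    """Heart-rate excursion: linear ramp, ictal plateau, exponential decay."""
    bump = np.zeros_like(t)
    if ramp > 0:
        rising = (t >= onset) & (t < onset + ramp)
        bump[rising] = hr_delta * (t[rising] - onset) / ramp
    plateau = (t >= onset + ramp) & (t < offset)
    bump[plateau] = hr_delta
    post = t >= offset
    bump[post] = hr_delta * np.exp(-(t[post] - offset) / decay_tau)
    return bump


def _beat_times(
    duration: float,
    hr_of_t,
    hrv_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """RR tachogram: walk beat-to-beat with jittered instantaneous rate."""
    times = []
    t = float(rng.uniform(0.0, 0.3))  # random phase of the first beat
    while t < duration:
        hr = float(hr_of_t(t)) + float(rng.normal(0.0, hrv_sd))
        hr = max(hr, 20.0)  # physiological floor, avoids runaway RR
        times.append(t)
        t += 60.0 / hr
    return np.asarray(times)


def _render_template_train(
    beat_times: np.ndarray,
    n_samples: int,
    fs: float,
    amplitude_gain=None,
) -> np.ndarray:
    signal = np.zeros(n_samples)
    for tb in beat_times:
        gain = 1.0 if amplitude_gain is None else float(amplitude_gain(tb))
        lo = max(0, int((tb - 0.40) * fs))
        hi = min(n_samples, int((tb + 0.65) * fs) + 1)
        if hi <= lo:
            continue
        tt = np.arange(lo, hi) / fs - tb
        seg = np.zeros_like(tt)
        for off, amp, sigma in _WAVES:
            seg += amp * np.exp(-0.5 * ((tt - off) / sigma) ** 2)
        signal[lo:hi] += gain * seg
    return signal


def generate_ecg(
    duration: float,
    hr_profile,
    fs: float = 256.0,
    seed: int = 0,
    hrv_sd: float = 0.0,
    noise_sd: float = 0.01,
) -> np.ndarray:
    """Generate a quasi-periodic PQRST train tracking ``hr_profile``.

    Parameters
    ----------
    duration : seconds of signal to produce (must be positive).
    hr_profile : scalar BPM or callable ``t -> BPM`` (positive everywhere).
    fs : sampling rate in Hz.
    seed : RNG seed; identical seeds give byte-identical signals.
    hrv_sd : beat-to-beat heart-rate SD in BPM.
    noise_sd : additive white measurement noise, mV.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    hr_of_t = hr_profile if callable(hr_profile) else (lambda t: hr_profile)
    probe = np.linspace(0.0, duration, 16)
    if any(hr_of_t(t) <= 0 for t in probe):
        raise ValueError("hr_profile must be positive everywhere")
    rng = np.random.default_rng(seed)
    beats = _beat_times(duration, hr_of_t, hrv_sd, rng)
    n = int(round(duration * fs))
    signal = _render_template_train(beats, n, fs)
    if noise_sd > 0:
        signal += rng.normal(0.0, noise_sd, size=n)
    return signal


def _render_recording(
    patient_id: str,
    recording_id: str,
    duration: float,
    baseline_hr: float,
    hrv_sd: float,
    seizures: list[dict],
    fs: float,
    seed: int,
    noise_sd: float = 0.01,
    morphology_gain: float = 0.0,
) -> Recording:
    """Render a full recording from its generation parameters.

    ``seizures`` entries carry onset, duration, hr_delta, ramp, decay_tau,
    seizure_type.  Regenerating from identical parameters reproduces the
    signal exactly, which is what makes seizure injection well-defined.
    """

    def hr_of_t(t):
        ts = np.atleast_1d(np.asarray(t, dtype=float))
        hr = np.full_like(ts, baseline_hr)
        for s in seizures:
            hr += _seizure_hr_bump(
                ts, s["onset"], s["onset"] + s["duration"], s["hr_delta"],
                s.get("ramp", 10.0), s.get("decay_tau", 30.0),
            )
        return hr if np.ndim(t) else float(hr[0])

    def gain_of_t(t):
        g = 1.0
        if morphology_gain:
            for s in seizures:
                if s["onset"] <= t < s["onset"] + s["duration"]:
                    g *= 1.0 + morphology_gain
        return g

    rng = np.random.default_rng(seed)
    beats = _beat_times(duration, hr_of_t, hrv_sd, rng)
    n = int(round(duration * fs))
    signal = _render_template_train(
        beats, n, fs, amplitude_gain=gain_of_t if morphology_gain else None
    )
    if noise_sd > 0:
        signal += rng.normal(0.0, noise_sd, size=n)
    annotations = [
        SeizureAnnotation(s["onset"], s["onset"] + s["duration"], s["seizure_type"])
        for s in seizures
    ]
    return Recording(
        patient_id=patient_id,
        recording_id=recording_id,
        signal=signal,
        sampling_rate=fs,
        annotations=annotations,
        meta={
            "duration": duration,
            "baseline_hr": baseline_hr,
            "hrv_sd": hrv_sd,
            "seizures": seizures,
            "seed": seed,
            "noise_sd": noise_sd,
            "morphology_gain": morphology_gain,
        },
    )


def make_recording(
    patient_id: str = "sub-000",
    recording_id: str = "run-01",
    duration: float = 360.0,
    baseline_hr: float = 70.0,
    hrv_sd: float = 3.0,
    fs: float = 256.0,
    seed: int = 0,
) -> Recording:
    """Baseline (seizure-free) synthetic recording."""
    return _render_recording(
        patient_id, recording_id, duration, baseline_hr, hrv_sd, [], fs, seed
    )


def inject_seizure(
    recording: Recording,
    onset: float,
    duration: float,
    hr_delta: float,
    ramp: float = 10.0,
    decay_tau: float = 30.0,
    seizure_type: str = "ia_nm",
    morphology_gain: float | None = None,
) -> tuple[Recording, SeizureAnnotation]:
    """Add an ictal heart-rate excursion to a synthetic recording.

    The trace is re-rendered from its stored tachogram parameters with the
    excursion included, so a zero-delta injection reproduces the original
    signal exactly.  Returns the new recording and the annotation.
    """
    if not recording.meta or "baseline_hr" not in recording.meta:
        raise ValueError("inject_seizure requires a generator-built recording")
    if onset < 0 or onset + duration > recording.duration + 1e-9:
        raise ValueError("seizure interval outside the recording")
    meta = recording.meta
    seizures = list(meta["seizures"]) + [
        {
            "onset": float(onset),
            "duration": float(duration),
            "hr_delta": float(hr_delta),
            "ramp": float(ramp),
            "decay_tau": float(decay_tau),
            "seizure_type": seizure_type,
        }
    ]
    new = _render_recording(
        recording.patient_id,
        recording.recording_id,
        meta["duration"],
        meta["baseline_hr"],
        meta["hrv_sd"],
        seizures,
        recording.sampling_rate,
        meta["seed"],
        noise_sd=meta.get("noise_sd", 0.01),
        morphology_gain=(
            meta.get("morphology_gain", 0.0)
            if morphology_gain is None
            else morphology_gain
        ),
    )
    return new, new.annotations[-1]


def inject_saturation(
    signal: np.ndarray,
    fraction: float,
    rail: float = 2.0,
    seed: int = 0,
    mean_run_s: float = 1.0,
    fs: float = 256.0,
) -> np.ndarray:
    """Clip exactly ``floor(fraction * N)`` samples to ±rail in contiguous runs.

    Run starts are seeded-random and non-overlapping; the clipped sign
    follows the local signal polarity, emulating electrode rail episodes.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction outside [0, 1]")
    sig = np.asarray(signal, dtype=float).copy()
    n = len(sig)
    n_clip = int(math.floor(fraction * n))
    if n_clip == 0:
        return sig
    rng = np.random.default_rng(seed)
    run_len = max(1, int(round(mean_run_s * fs)))
    taken = np.zeros(n, dtype=bool)
    clipped = 0
    attempts = 0
    while clipped < n_clip and attempts < 10_000:
        attempts += 1
        length = min(run_len, n_clip - clipped)
        start = int(rng.integers(0, max(1, n - length + 1)))
        span = slice(start, start + length)
        if taken[span].any():
            continue
        sign = 1.0 if float(np.mean(sig[span])) >= 0 else -1.0
        sig[span] = sign * rail
        taken[span] = True
        clipped += length
    if clipped < n_clip:  # dense fractions: fill remaining free samples
        free = np.flatnonzero(~taken)[: n_clip - clipped]
        sig[free] = rail
    return sig


def generate_cohort(spec: CohortSpec) -> tuple[list[Recording], pd.DataFrame]:
    """Generate all recordings plus a patient/recording manifest.

    The manifest lists patient id, ground-truth responder status, injected
    heart-rate delta, seizure types and per-recording bookkeeping; identical
    specs (including seed) give identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    n_resp = int(round(spec.responder_fraction * spec.n_patients))
    responder_flags = np.zeros(spec.n_patients, dtype=bool)
    responder_flags[rng.permutation(spec.n_patients)[:n_resp]] = True

    labels = sorted(spec.type_distribution)
    probs = np.array([spec.type_distribution[k] for k in labels])
    lo, hi = spec.seizure_duration_range

    recordings: list[Recording] = []
    rows = []
    for p in range(spec.n_patients):
        patient_id = f"sub-{p + 1:03d}"
        is_resp = bool(responder_flags[p])
        hr_delta = spec.responder_hr_delta if is_resp else spec.nonresponder_hr_delta
        for r in range(spec.recordings_per_patient):
            recording_id = f"{patient_id}_run-{r + 1:02d}"
            rec_seed = int(rng.integers(0, 2**31 - 1))
            rec = make_recording(
                patient_id,
                recording_id,
                spec.recording_duration,
                spec.baseline_hr,
                spec.hrv_sd,
                spec.sampling_rate,
                rec_seed,
            )
            # one seizure per equal slot, with pre/post context margins
            slot = spec.recording_duration / spec.seizures_per_recording
            types = []
            for k in range(spec.seizures_per_recording):
                dur = float(rng.uniform(lo, hi))
                margin = 60.0
                lo_on = k * slot + margin
                hi_on = (k + 1) * slot - dur - margin
                onset = float(rng.uniform(lo_on, max(lo_on + 1e-6, hi_on)))
                stype = str(rng.choice(labels, p=probs))
                types.append(stype)
                rec, _ = inject_seizure(
                    rec, onset, dur, hr_delta, seizure_type=stype
                )
            if spec.saturation_fraction > 0:
                sat_seed = int(rng.integers(0, 2**31 - 1))
                rec.signal = inject_saturation(
                    rec.signal,
                    spec.saturation_fraction,
                    seed=sat_seed,
                    fs=spec.sampling_rate,
                )
                rec.meta["saturation_fraction"] = spec.saturation_fraction
            recordings.append(rec)
            rows.append(
                {
                    "patient_id": patient_id,
                    "recording_id": recording_id,
                    "is_responder": is_resp,
                    "hr_delta": hr_delta,
                    "n_seizures": spec.seizures_per_recording,
                    "seizure_types": ";".join(types),
                    "duration_s": spec.recording_duration,
                    "saturation_fraction": spec.saturation_fraction,
                }
            )
    manifest = pd.DataFrame(rows)
    return recordings, manifest


def write_cohort(
    recordings: list[Recording],
    manifest: pd.DataFrame,
    outdir,
) -> pd.DataFrame:
    """Write EDF signals, a TSV annotation table and a CSV manifest.

    Returns the manifest augmented with file paths.
    """
    from pathlib import Path

    from .edf import write_edf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    ann_rows = []
    for rec in recordings:
        path = outdir / f"{rec.recording_id}.edf"
        write_edf(path, rec.signal, rec.sampling_rate)
        paths.append(str(path))
        for ann in rec.annotations:
            ann_rows.append(
                {
                    "recording_id": rec.recording_id,
                    "onset_s": ann.onset,
                    "offset_s": ann.offset,
                    "seizure_type": ann.seizure_type,
                }
            )
    manifest = manifest.copy()
    manifest["path"] = paths
    pd.DataFrame(
        ann_rows, columns=["recording_id", "onset_s", "offset_s", "seizure_type"]
    ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def write_csv_signal(recording: Recording, path) -> None:
    """Two-column plain-text dialect (time_s, amplitude_mV) for tiny fixtures."""
    t = np.arange(len(recording.signal)) / recording.sampling_rate
    pd.DataFrame({"time_s": t, "amplitude_mV": recording.signal}).to_csv(
        path, index=False
    )
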