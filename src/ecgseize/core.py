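"""Shared domain containers for the ECG seizure-detection benchmark.

Times are seconds from recording start, intervals half-open ``[start, end)``.
Signals are single-lead ECG amplitudes in millivolt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Seizure-type vocabulary of the benchmark test set (focal aware / impaired
#: awareness, motor / non-motor subtypes, focal-to-bilateral tonic-clonic).
SEIZURE_TYPES = (
    "ua_nm",
    "ia",
    "f2b",
    "a_um",
    "a_nm",
    "a_m_hyperkinetic",
    "ia_m_automatisms",
    "ia_m_hyperkinetic",
    "ia_nm",
)


@dataclass(frozen=True)
class SeizureAnnotation:
    """One annotated seizure: ``[onset, offset)`` seconds plus a type label."""

    onset: float
    offset: float
    seizure_type: str = "ia_nm"

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError(
                f"seizure offset ({self.offset}) must exceed onset ({self.onset})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class Recording:
    """A single patient's single-lead ECG trace with its annotations."""

    patient_id: str
    recording_id: str
    signal: np.ndarray
    sampling_rate: float
    annotations: list[SeizureAnnotation] = field(default_factory=list)
    #: generation parameters for synthetic recordings (provenance / re-render)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1:
            raise ValueError("signal must be one-dimensional")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.annotations = sorted(self.annotations, key=lambda a: a.onset)
        dur = self.duration
        for ann in self.annotations:
            if ann.onset < 0 or ann.offset > dur + 1e-9:
                raise ValueError(
                    f"annotation [{ann.onset}, {ann.offset}) outside recording "
                    f"of duration {dur:.3f}s"
                )

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return len(self.signal) / self.sampling_rate


@dataclass
class AnomalyEvent:
    """A detector output on the 8 Hz timeline.

    ``index`` is the sample position of the event (representative index after
    clustering), ``score`` the discord distance or masked negative
    log-likelihood, ``interval`` the event span in seconds when known.
    """

    index: int
    score: float
    detector: str = "mp"
    stage: str = "raw"
    interval: tuple[float, float] | None = None

    def time_s(self, fs: float) -> float:
        return self.index / fs


@dataclass
class PreprocessedSeries:
    """Band-passed, downsampled series ready for the anomaly detectors."""

    samples: np.ndarray
    sampling_rate: float
    source_recording: str = ""
    filter_params: tuple[float, float, int] = (0.5, 40.0, 4)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class QCReport:
    """Quality-control verdict for one recording."""

    recording_id: str
    has_ecg: bool
    saturation_fraction: float
    excluded: bool
    exclusion_reason: str  # none | no_ecg | saturated

    def __post_init__(self) -> None:
        if self.excluded != (self.exclusion_reason != "none"):
            raise ValueError("excluded flag inconsistent with exclusion_reason")
        if not 0.0 <= self.saturation_fraction <= 1.0:
            raise ValueError("saturation_fraction outside [0, 1]")


def hms(sensitivity_pct: float, far_per_hour: float) -> float:
    """Harmonic Mean Score: ``sensitivity(%) - 0.4 * FAR(FA/h)``.

    The composite benchmark metric trading detection rate against alarm
    burden; unclipped, so heavy alarm rates drive it negative.
    """
    return float(sensitivity_pct) - 0.4 * float(far_per_hour)


@dataclass
class MatchingMode:
    """Event-matching rule: strict ictal overlap or the seizure detection
    window (SDW) spanning ``sdw_pre`` s before to ``sdw_post`` s after onset."""

    mode: str = "strict"  # strict | sdw
    sdw_pre: float = 300.0
    sdw_post: float = 180.0

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "sdw"):
            raise ValueError("mode must be 'strict' or 'sdw'")
        if self.sdw_pre < 0 or self.sdw_post < 0:
            raise ValueError("SDW spans must be nonnegative")


@dataclass
class PatientMetrics:
    """Per-patient sensitivity / FAR / HMS under a stated matching mode."""

    patient_id: str
    sensitivity: float | None  # percent; None when the patient has no seizures
    far: float  # false alarms per hour
    n_seizures: int
    recorded_hours: float
    mode: str = "strict"
    hms: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.far < 0:
            raise ValueError("FAR must be nonnegative")
        if self.sensitivity is not None and not 0 <= self.sensitivity <= 100:
            raise ValueError("sensitivity must lie in [0, 100]")
        if self.sensitivity is None:
            self.hms = None
        else:
            self.hms = hms(self.sensitivity, self.far)


@dataclass
class ResponderStatus:
    """Responder flag (> 50 BPM ictal heart-rate excursion) with the
    RR-window bookkeeping that justified it."""

    patient_id: str
    is_responder: bool
    max_hr_change: float
    rr_count_used: int
    window_extended: bool

    def __post_init__(self) -> None:
        if self.is_responder != (self.max_hr_change > 50.0):
            raise ValueError("is_responder inconsistent with max_hr_change")


@dataclass
class McNemarResult:
    """Yates-corrected McNemar comparison of two detectors' per-seizure hits."""

    n10: int
    n01: int
    chi2: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class BootstrapCI:
    """Patient-level bootstrap percentile interval for one metric."""

    metric: str
    lower: float
    upper: float
    iterations: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")
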