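"""End-to-end benchmark runner: generation -> QC -> preprocessing ->
detection -> clustering post-processing -> evaluation.

The cohort is split by patient into train and test; every data-driven
choice (detector operating point, clustering gap) is made on train
patients only, then applied unchanged to the held-out test patients.
Metrics are reported per detector and optimization objective, under both
strict and SDW matching, for all patients and the responder subset.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import clustering, evaluation, io
from .core import MatchingMode, PatientMetrics, Recording
from .matrix_profile import MatrixProfileDetector
from .synthetic import CohortSpec, generate_cohort
from .tvq import TimeVQVAEDetector

log = logging.getLogger("ecgseize")

REPORT_COLUMNS = [
    "detector",
    "objective",
    "mode",
    "operating_point",
    "delta_t",
    "sensitivity_all",
    "far_all",
    "hms_all",
    "sensitivity_responders",
    "far_responders",
    "hms_responders",
    "n_test_patients",
]


@dataclass
class RunConfig:
    """Benchmark configuration; defaults describe the desk-scale cohort."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    train_fraction: float = 0.75
    train_patients: list[str] | None = None
    test_patients: list[str] | None = None
    mp_percentile_grid: tuple = (0.95, 0.98, 0.99)
    mp_params: dict = field(default_factory=lambda: {"m": 80, "min_n": 2, "max_gap_s": 2.0})
    madrid_percentile_grid: tuple = (0.95, 0.98, 0.99)
    madrid_params: dict = field(
        default_factory=lambda: {"m_grid": (24, 48, 80, 120), "top_k": 5}
    )
    tvq_percentile_grid: tuple = (0.95, 0.98, 0.99)
    tvq_params: dict = field(
        default_factory=lambda: {"stage1_steps": 250, "stage2_steps": 250}
    )
    delta_t_grid: tuple = (2, 5, 10, 30, 60)
    sdw_pre: float = 300.0
    sdw_post: float = 180.0
    bootstrap_iterations: int = 1000
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def split_patients(
    patient_ids, train_fraction=0.75, train=None, test=None
) -> tuple[list[str], list[str]]:
    """Patient-level train/test split; overlapping explicit lists hard-fail."""
    ids = sorted(set(patient_ids))
    if train is not None or test is not None:
        train = sorted(train or [])
        test = sorted(test or [t for t in ids if t not in train])
        overlap = set(train) & set(test)
        if overlap:
            raise ValueError(f"train/test patient overlap: {sorted(overlap)}")
        return train, test
    n_train = max(1, min(len(ids) - 1, math.ceil(train_fraction * len(ids))))
    return ids[:n_train], ids[n_train:]


def sweep_operating_points(table: pd.DataFrame, objective: str) -> int:
    """Pick the operating point maximizing the objective on train patients.

    FAR is minimized (ties broken by higher sensitivity); sensitivity and
    HMS are maximized (ties broken by lower FAR, then table order).
    """
    if len(table) == 0:
        raise ValueError("no candidate operating points")
    if objective == "far":
        order = table.sort_values(
            ["far", "sensitivity"], ascending=[True, False], kind="stable"
        )
    elif objective == "sensitivity":
        order = table.sort_values(
            ["sensitivity", "far"], ascending=[False, True], kind="stable"
        )
    elif objective == "hms":
        order = table.sort_values(
            ["hms", "far"], ascending=[False, True], kind="stable"
        )
    else:
        raise ValueError(f"unknown objective {objective!r}")
    return int(order.index[0])


def evaluate_patients(
    detections_by_recording: dict[str, list[tuple[float, float]]],
    recordings: list[Recording],
    mode: MatchingMode,
) -> list[PatientMetrics]:
    """Pool each patient's recordings and compute their metrics."""
    by_patient: dict[str, dict] = {}
    for rec in recordings:
        acc = by_patient.setdefault(
            rec.patient_id, {"tp": 0, "fn": 0, "fp": 0, "hours": 0.0}
        )
        match = evaluation.match_events(
            detections_by_recording.get(rec.recording_id, []),
            rec.annotations,
            mode,
        )
        acc["tp"] += match.tp
        acc["fn"] += match.fn
        acc["fp"] += match.fp
        acc["hours"] += rec.duration / 3600.0
    out = []
    for pid in sorted(by_patient):
        acc = by_patient[pid]
        n = acc["tp"] + acc["fn"]
        sens = 100.0 * acc["tp"] / n if n else None
        out.append(
            PatientMetrics(
                patient_id=pid,
                sensitivity=sens,
                far=acc["fp"] / acc["hours"],
                n_seizures=n,
                recorded_hours=acc["hours"],
                mode=mode.mode,
            )
        )
    return out


def _mean_metrics(per_patient: list[PatientMetrics]) -> dict:
    defined = [p for p in per_patient if p.sensitivity is not None]
    return {
        "sensitivity": (
            float(np.mean([p.sensitivity for p in defined])) if defined else float("nan")
        ),
        "far": float(np.mean([p.far for p in per_patient])) if per_patient else float("nan"),
        "hms": float(np.mean([p.hms for p in defined])) if defined else float("nan"),
    }


def _events_to_intervals(events, fs: float) -> list[tuple[float, float]]:
    out = []
    for e in events:
        if e.interval is not None:
            out.append((float(e.interval[0]), float(e.interval[1])))
        else:
            t = e.index / fs
            out.append((t, t))
    return out


class _Pipeline:
    """Caches per-recording detector state so operating-point sweeps and the
    final test evaluation reuse the expensive computations."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.fs = 8.0
        cohort_recs, manifest = generate_cohort(config.cohort)
        self.manifest = manifest
        self.qc_reports = [io.qc_recording(r) for r in cohort_recs]
        excluded = {q.recording_id for q in self.qc_reports if q.excluded}
        if excluded:
            log.info("QC excluded %d recordings", len(excluded))
        self.recordings = [
            r for r in cohort_recs if r.recording_id not in excluded
        ]
        self.series = {
            r.recording_id: io.preprocess(
                r.signal, r.sampling_rate, source_recording=r.recording_id
            ).samples
            for r in self.recordings
        }
        self.train_ids, self.test_ids = split_patients(
            [r.patient_id for r in self.recordings],
            config.train_fraction,
            config.train_patients,
            config.test_patients,
        )
        self.responders = self._classify_responders()
        self.sdw = MatchingMode("sdw", config.sdw_pre, config.sdw_post)

    def _classify_responders(self) -> dict[str, bool]:
        out = {}
        for rec in self.recordings:
            if rec.patient_id in out or not rec.annotations:
                continue
            status = evaluation.classify_responder(rec)
            out[rec.patient_id] = status.is_responder
        return out

    def recs(self, patient_ids) -> list[Recording]:
        keep = set(patient_ids)
        return [r for r in self.recordings if r.patient_id in keep]

    # -- per-detector detection caches --------------------------------
    def mp_detections(self, percentile: float) -> dict:
        if not hasattr(self, "_mp"):
            self._mp = {}
            p = self.config.mp_params
            for rid, x in self.series.items():
                det = MatrixProfileDetector(fs=self.fs, **p)
                self._mp[rid] = det.fit(x)
        from .matrix_profile import cluster_min_run, select_discords

        p = self.config.mp_params
        out = {}
        for rid, det in self._mp.items():
            raw = select_discords(det.profile_, p["m"], percentile)
            events = cluster_min_run(
                raw, p["min_n"], p["max_gap_s"], self.fs, span_s=p["m"] / self.fs
            )
            out[rid] = _events_to_intervals(events, self.fs)
        return out

    def madrid_raw(self, percentile: float) -> dict:
        if not hasattr(self, "_madrid_tables"):
            from .madrid import multi_length_discords

            self._madrid_tables = {
                rid: multi_length_discords(
                    x, m_grid=self.config.madrid_params["m_grid"]
                )
                for rid, x in self.series.items()
            }
        from .madrid import select_anomalies

        return {
            rid: select_anomalies(
                table,
                percentile,
                self.config.madrid_params["top_k"],
                fs=self.fs,
            )
            for rid, table in self._madrid_tables.items()
        }

    def tvq_fit(self) -> TimeVQVAEDetector:
        if not hasattr(self, "_tvq"):
            segments = []
            for rec in self.recs(self.train_ids):
                x = self.series[rec.recording_id]
                segments.extend(
                    _normal_segments(x, rec, self.sdw, self.fs)
                )
            det = TimeVQVAEDetector(
                fs=self.fs, seed=self.config.seed, **self.config.tvq_params
            )
            det.fit(segments)
            self._tvq = det
            self._tvq_maps = {
                rid: det.score_map(x) for rid, x in self.series.items()
            }
        return self._tvq

    def tvq_detections(self, tau_percentile: float, delta_t: float) -> dict:
        det = self.tvq_fit()
        tau = float(np.quantile(det.train_scores_, tau_percentile))
        from .tvq import detect as tvq_detect

        out = {}
        for rid, smap in self._tvq_maps.items():
            n = len(self.series[rid])
            events = tvq_detect(
                smap, tau, n, delta_t, self.config.tvq_params.get(
                    "coverage_limit", 0.5
                )
            )
            out[rid] = _events_to_intervals(events, self.fs)
        return out


def _normal_segments(x, rec: Recording, sdw: MatchingMode, fs: float, min_len=160):
    """Chunks of the series outside every seizure detection window."""
    blocked = np.zeros(len(x), dtype=bool)
    for ann in rec.annotations:
        w0, w1 = evaluation.seizure_window(ann, sdw)
        i0 = max(0, int(w0 * fs))
        i1 = min(len(x), int(np.ceil(w1 * fs)))
        blocked[i0:i1] = True
    segments = []
    start = None
    for i, b in enumerate(np.append(blocked, True)):
        if not b and start is None:
            start = i
        elif b and start is not None:
            if i - start >= min_len:
                segments.append(x[start:i])
            start = None
    return segments


def _select_delta_t_for(
    raw_times: dict, pipeline: _Pipeline, train_recs, grid
) -> float:
    windows = [
        [
            evaluation.seizure_window(a, MatchingMode("strict"))
            for a in rec.annotations
        ]
        for rec in train_recs
    ]
    times = [sorted(raw_times.get(rec.recording_id, [])) for rec in train_recs]
    chosen, _ = clustering.select_delta_t(times, windows, candidate_grid=grid)
    return chosen


def run_benchmark(config: RunConfig | None = None) -> dict:
    """Run the full synthetic benchmark and return report tables.

    Returns a dict with ``report`` (one row per detector x objective x
    matching mode), ``responders``, ``qc``, ``selection`` (the train-side
    choices) and provenance (config hash, seed).
    """
    config = config or RunConfig()
    pipe = _Pipeline(config)
    train_recs = pipe.recs(pipe.train_ids)
    test_recs = pipe.recs(pipe.test_ids)
    strict = MatchingMode("strict")
    modes = {"strict": strict, "sdw": pipe.sdw}
    grid = [d for d in config.delta_t_grid]

    # --- candidate detections per detector/operating point ------------
    candidates: dict[str, dict] = {"mp": {}, "madrid": {}, "tvq": {}}
    for pct in config.mp_percentile_grid:
        candidates["mp"][pct] = (pipe.mp_detections(pct), None)
    for pct in config.madrid_percentile_grid:
        raw = pipe.madrid_raw(pct)
        raw_times = {
            rid: [e.index / pipe.fs for e in evs] for rid, evs in raw.items()
        }
        dt = _select_delta_t_for(raw_times, pipe, train_recs, grid)
        dets = {}
        for rid, evs in raw.items():
            times = [e.index / pipe.fs for e in evs]
            reps = clustering.cluster_representatives(times, dt)
            dets[rid] = [
                (evs[i].interval[0], evs[i].interval[1]) for i in reps
            ]
        candidates["madrid"][pct] = (dets, dt)
    pipe.tvq_fit()
    for pct in config.tvq_percentile_grid:
        tau = float(np.quantile(pipe._tvq.train_scores_, pct))
        raw_times = {}
        for rid, smap in pipe._tvq_maps.items():
            per_sample = smap.per_sample(len(pipe.series[rid]))
            raw_times[rid] = (np.flatnonzero(per_sample > tau) / pipe.fs).tolist()
        dt = _select_delta_t_for(raw_times, pipe, train_recs, grid)
        candidates["tvq"][pct] = (pipe.tvq_detections(pct, dt), dt)

    # --- operating-point selection on train, evaluation on test -------
    rows = []
    selection: dict[str, dict] = {}
    for detector, ops in candidates.items():
        for mode_name, mode in modes.items():
            table = pd.DataFrame(
                [
                    {
                        "op": op,
                        **_mean_metrics(
                            evaluate_patients(dets, train_recs, mode)
                        ),
                    }
                    for op, (dets, _) in ops.items()
                ]
            )
            for objective in ("far", "sensitivity", "hms"):
                pick = sweep_operating_points(table, objective)
                op = table.loc[pick, "op"]
                dets, dt = ops[op]
                per_patient = evaluate_patients(dets, test_recs, mode)
                resp = [
                    p for p in per_patient if pipe.responders.get(p.patient_id)
                ]
                overall = _mean_metrics(per_patient)
                responders = _mean_metrics(resp) if resp else dict.fromkeys(
                    ("sensitivity", "far", "hms"), float("nan")
                )
                selection.setdefault(detector, {})[
                    f"{mode_name}:{objective}"
                ] = {"op": float(op), "delta_t": dt}
                rows.append(
                    {
                        "detector": detector,
                        "objective": objective,
                        "mode": mode_name,
                        "operating_point": float(op),
                        "delta_t": dt,
                        "sensitivity_all": overall["sensitivity"],
                        "far_all": overall["far"],
                        "hms_all": overall["hms"],
                        "sensitivity_responders": responders["sensitivity"],
                        "far_responders": responders["far"],
                        "hms_responders": responders["hms"],
                        "n_test_patients": len(per_patient),
                    }
                )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return {
        "report": report,
        "responders": pipe.responders,
        "qc": io.qc_table(pipe.qc_reports),
        "selection": selection,
        "train_patients": pipe.train_ids,
        "test_patients": pipe.test_ids,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
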