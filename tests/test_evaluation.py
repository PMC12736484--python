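"""Event matching, metrics, McNemar, responder logic and bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest

from ecgseize import evaluation
from ecgseize.core import (
    MatchingMode,
    PatientMetrics,
    QCReport,
    Recording,
    SeizureAnnotation,
    hms,
)
from ecgseize.synthetic import generate_ecg, inject_seizure, make_recording

SDW = MatchingMode("sdw")


class TestMatchEvents:
    def test_pre_ictal_detection_fn_strict_tp_sdw(self):
        seizures = [SeizureAnnotation(600.0, 660.0)]
        det = [(360.0, 361.0)]  # four minutes before onset
        strict = evaluation.match_events(det, seizures, "strict")
        sdw = evaluation.match_events(det, seizures, SDW)
        assert strict.tp == 0 and strict.fn == 1 and strict.fp == 1
        assert sdw.tp == 1 and sdw.fn == 0 and sdw.fp == 0

    def test_detection_at_onset_tp_in_both_modes(self):
        seizures = [SeizureAnnotation(100.0, 160.0)]
        for mode in ("strict", SDW):
            match = evaluation.match_events([(100.0, 100.0)], seizures, mode)
            assert match.tp == 1 and match.fp == 0

    def test_no_detections(self):
        match = evaluation.match_events([], [SeizureAnnotation(10.0, 20.0)])
        assert match.tp == 0 and match.fn == 1 and match.fp == 0

    def test_one_detection_credits_multiple_seizures(self):
        seizures = [SeizureAnnotation(10.0, 20.0), SeizureAnnotation(25.0, 35.0)]
        match = evaluation.match_events([(15.0, 30.0)], seizures, "strict")
        assert match.tp == 2 and match.fp == 0

    def test_multiple_detections_count_one_tp_no_fp(self):
        seizures = [SeizureAnnotation(10.0, 20.0)]
        match = evaluation.match_events(
            [(11.0, 12.0), (15.0, 16.0), (18.0, 19.0)], seizures, "strict"
        )
        assert match.tp == 1 and match.fp == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_sdw_dominates_strict(self, seed):
        rng = np.random.default_rng(seed)
        seizures = [
            SeizureAnnotation(float(o), float(o + 30))
            for o in np.sort(rng.uniform(400, 3000, size=3))
        ]
        starts = rng.uniform(0, 3600, size=20)
        dets = [(float(s), float(s + rng.uniform(0, 10))) for s in starts]
        strict = evaluation.match_events(dets, seizures, "strict")
        sdw = evaluation.match_events(dets, seizures, SDW)
        assert sdw.tp >= strict.tp
        assert sdw.fp <= strict.fp


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "sens,far,expected",
        [(19.63, 1.92, 18.86), (82.79, 26.12, 72.34), (0.0, 0.0, 0.0)],
    )
    def test_hms_closed_form(self, sens, far, expected):
        assert round(hms(sens, far), 2) == expected

    def test_patient_metrics_consistency(self):
        seizures = [SeizureAnnotation(10.0, 20.0), SeizureAnnotation(50.0, 60.0)]
        match = evaluation.match_events([(12.0, 13.0), (90.0, 91.0)], seizures)
        pm = evaluation.compute_metrics(match, recorded_hours=2.0, patient_id="p")
        assert pm.sensitivity == pytest.approx(50.0)
        assert pm.far == pytest.approx(0.5)
        assert pm.hms == pytest.approx(50.0 - 0.4 * 0.5)

    def test_zero_seizures_undefined_sensitivity(self):
        match = evaluation.match_events([(5.0, 6.0)], [])
        pm = evaluation.compute_metrics(match, 1.0)
        assert pm.sensitivity is None and pm.hms is None
        assert pm.far == pytest.approx(1.0)

    def test_hms_identity_enforced_at_construction(self):
        pm = PatientMetrics("p", 80.0, 5.0, 4, 2.0)
        assert pm.hms == pytest.approx(80.0 - 2.0)


class TestMcNemar:
    @pytest.mark.parametrize(
        "n10,n01,chi2", [(15, 5, 4.05), (8, 8, 0.0625), (1, 0, 0.0)]
    )
    def test_yates_statistic(self, n10, n01, chi2):
        res = evaluation.mcnemar(n10, n01)
        assert res.chi2 == pytest.approx(chi2)
        assert 0.0 <= res.p <= 1.0

    def test_symmetry(self):
        assert evaluation.mcnemar(12, 3).chi2 == evaluation.mcnemar(3, 12).chi2

    def test_no_discordance(self):
        res = evaluation.mcnemar(0, 0)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_from_outcome_vectors(self):
        a = [True, True, False, True]
        b = [True, False, True, False]
        res = evaluation.mcnemar_from_outcomes(a, b)
        assert (res.n10, res.n01) == (2, 1)


class TestRPeaks:
    def test_sixty_bpm_rr_about_one_second(self):
        sig = generate_ecg(60.0, 60.0, fs=256, seed=1, noise_sd=0.005)
        peaks = evaluation.detect_r_peaks(sig, 256.0)
        rr = evaluation.rr_intervals(peaks)
        assert 57 <= len(rr) <= 60
        assert np.mean(rr) == pytest.approx(1.0, abs=0.02)

    def test_hundred_twenty_bpm_rr_halves(self):
        sig = generate_ecg(60.0, 120.0, fs=256, seed=1, noise_sd=0.005)
        rr = evaluation.rr_intervals(evaluation.detect_r_peaks(sig, 256.0))
        assert np.mean(rr) == pytest.approx(0.5, abs=0.02)

    def test_flat_line_yields_no_peaks(self):
        rr = evaluation.rr_intervals(
            evaluation.detect_r_peaks(np.zeros(2560), 256.0)
        )
        assert len(rr) == 0


class TestClassifyResponder:
    def test_responder_recovered(self):
        rec = make_recording(duration=360.0, seed=21)
        rec, _ = inject_seizure(rec, 150.0, 45.0, hr_delta=70.0)
        status = evaluation.classify_responder(rec)
        assert status.is_responder
        assert status.max_hr_change > 50.0
        assert status.rr_count_used >= 100

    def test_nonresponder_recovered(self):
        rec = make_recording(duration=360.0, seed=22)
        rec, _ = inject_seizure(rec, 150.0, 45.0, hr_delta=20.0)
        status = evaluation.classify_responder(rec)
        assert not status.is_responder

    def test_constant_heart_rate_is_nonresponder(self):
        rec = make_recording(duration=360.0, hrv_sd=0.0, seed=23)
        rec.annotations = [SeizureAnnotation(150.0, 195.0)]
        status = evaluation.classify_responder(rec)
        assert status.max_hr_change < 10.0
        assert not status.is_responder

    def test_short_seizure_extends_window(self):
        rec = make_recording(duration=360.0, seed=24)
        rec, _ = inject_seizure(rec, 170.0, 10.0, hr_delta=70.0)
        status = evaluation.classify_responder(rec)
        assert status.window_extended
        assert status.rr_count_used >= 100


class TestBootstrap:
    def test_identical_values_give_point_interval(self):
        pms = [PatientMetrics(str(i), 70.0, 1.0, 2, 1.0) for i in range(5)]
        ci = evaluation.bootstrap_ci(pms, "sensitivity", 200, seed=0)
        assert ci.lower == ci.upper == pytest.approx(70.0)

    def test_two_extreme_patients_span_full_range(self):
        pms = [
            PatientMetrics("a", 0.0, 0.0, 1, 1.0),
            PatientMetrics("b", 100.0, 0.0, 1, 1.0),
        ]
        ci = evaluation.bootstrap_ci(pms, "sensitivity", 2000, seed=1)
        assert ci.lower == pytest.approx(0.0)
        assert ci.upper == pytest.approx(100.0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        pms = [
            PatientMetrics(str(i), float(v), 0.0, 1, 1.0)
            for i, v in enumerate(rng.uniform(0, 100, size=8))
        ]
        a = evaluation.bootstrap_ci(pms, "sensitivity", 500, seed=3)
        b = evaluation.bootstrap_ci(pms, "sensitivity", 500, seed=3)
        assert (a.lower, a.upper) == (b.lower, b.upper)


class TestSeizureTypes:
    def test_mean_across_models(self):
        detected = {
            "mp": [True, True, False, False],
            "madrid": [True, True, True, False],
            "tvq": [True, False, False, False],
        }
        table = evaluation.seizure_type_sensitivity(detected, ["f2b"] * 4)
        row = table.iloc[0]
        assert row["mean_sensitivity"] == pytest.approx((50 + 75 + 25) / 3)

    def test_absent_type_omitted_and_unknown_grouped(self):
        detected = {"mp": [True, False]}
        table = evaluation.seizure_type_sensitivity(
            detected, ["f2b", "weird"], known_types=("f2b", "ia_nm")
        )
        assert set(table["seizure_type"]) == {"f2b", "other"}


class TestExclusionBookkeeping:
    def test_usable_count_arithmetic(self):
        assert evaluation.usable_seizure_count(886, 27, 3) == 856
        assert evaluation.usable_seizure_count(10, 0, 0) == 10

    def test_table_based_bookkeeping_matches_ground_truth(self):
        seizures = pd.DataFrame(
            {
                "recording_id": ["r1", "r1", "r2", "r3", "r4"],
                "patient_id": ["p1", "p1", "p2", "p3", "p4"],
            }
        )
        qc = [
            QCReport("r1", True, 0.0, False, "none"),
            QCReport("r2", True, 0.2, True, "saturated"),
            QCReport("r3", False, 0.0, True, "no_ecg"),
            QCReport("r4", True, 0.15, True, "saturated"),
        ]
        out = evaluation.exclusion_bookkeeping(seizures, qc)
        assert out["annotated"] == 5
        assert out["no_ecg_losses"] == 1
        assert out["saturation_losses"] == 2
        assert out["usable"] == 2
        assert out["usable_patients"] == ["p1"]

    def test_unknown_recording_is_integrity_error(self):
        seizures = pd.DataFrame(
            {"recording_id": ["ghost"], "patient_id": ["p1"]}
        )
        with pytest.raises(ValueError):
            evaluation.exclusion_bookkeeping(seizures, [])
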