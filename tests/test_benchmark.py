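"""Benchmark orchestration: splits, operating-point sweeps, leakage, CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from ecgseize.benchmark import (
    REPORT_COLUMNS,
    RunConfig,
    run_benchmark,
    split_patients,
    sweep_operating_points,
)
from ecgseize.cli import main as cli_main
from ecgseize.synthetic import CohortSpec


def tiny_config(**kwargs):
    cohort = CohortSpec(
        n_patients=4,
        recording_duration=300.0,
        seizure_duration_range=(25.0, 40.0),
        seed=5,
    )
    defaults = dict(
        cohort=cohort,
        mp_percentile_grid=(0.95, 0.99),
        madrid_percentile_grid=(0.95, 0.99),
        tvq_percentile_grid=(0.95, 0.99),
        tvq_params={"stage1_steps": 60, "stage2_steps": 60},
        delta_t_grid=(5, 30),
        seed=5,
    )
    defaults.update(kwargs)
    return RunConfig(**defaults)


class TestSplitPatients:
    def test_fraction_split(self):
        train, test = split_patients([f"p{i}" for i in range(8)], 0.75)
        assert len(train) == 6 and len(test) == 2
        assert not set(train) & set(test)

    def test_explicit_overlap_hard_fails(self):
        with pytest.raises(ValueError):
            split_patients(["a", "b", "c"], train=["a", "b"], test=["b", "c"])

    def test_explicit_lists_respected(self):
        train, test = split_patients(["a", "b", "c"], train=["a"], test=["b", "c"])
        assert train == ["a"] and test == ["b", "c"]


class TestSweepOperatingPoints:
    def _table(self):
        return pd.DataFrame(
            {
                "op": [0.9, 0.95, 0.99],
                "sensitivity": [90.0, 80.0, 40.0],
                "far": [10.0, 2.0, 2.0],
                "hms": [86.0, 79.2, 39.2],
            }
        )

    def test_dominant_candidate_wins_everywhere(self):
        table = pd.DataFrame(
            {
                "op": [1, 2],
                "sensitivity": [90.0, 50.0],
                "far": [1.0, 5.0],
                "hms": [89.6, 48.0],
            }
        )
        for objective in ("sensitivity", "far", "hms"):
            assert sweep_operating_points(table, objective) == 0

    def test_far_tie_broken_by_sensitivity(self):
        pick = sweep_operating_points(self._table(), "far")
        assert self._table().loc[pick, "op"] == 0.95

    def test_hms_is_exhaustive_argmax(self):
        table = self._table()
        pick = sweep_operating_points(table, "hms")
        assert table.loc[pick, "hms"] == table["hms"].max()

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            sweep_operating_points(pd.DataFrame(), "hms")
        with pytest.raises(ValueError):
            sweep_operating_points(self._table(), "accuracy")


@pytest.fixture(scope="module")
def tiny_result():
    return run_benchmark(tiny_config())


class TestRunBenchmark:
    def test_report_schema_stable(self, tiny_result):
        report = tiny_result["report"]
        assert list(report.columns) == REPORT_COLUMNS
        assert set(report["detector"]) == {"mp", "madrid", "tvq"}
        assert set(report["mode"]) == {"strict", "sdw"}
        assert len(report) == 18  # 3 detectors x 3 objectives x 2 modes

    def test_sdw_sensitivity_dominates_strict(self, tiny_result):
        report = tiny_result["report"]
        for (det, obj), grp in report.groupby(["detector", "objective"]):
            strict = grp[grp["mode"] == "strict"]["sensitivity_all"].iloc[0]
            sdw = grp[grp["mode"] == "sdw"]["sensitivity_all"].iloc[0]
            assert sdw >= strict - 1e-9

    def test_train_test_patient_partition(self, tiny_result):
        assert not set(tiny_result["train_patients"]) & set(
            tiny_result["test_patients"]
        )

    def test_selection_ignores_test_patients(self):
        """Changing which patients are held out must not change the
        train-side configuration choices (no test leakage)."""
        cohort = CohortSpec(
            n_patients=5,
            recording_duration=300.0,
            seizure_duration_range=(25.0, 40.0),
            seed=5,
        )
        ids = [f"sub-{i + 1:03d}" for i in range(5)]
        a = run_benchmark(
            tiny_config(
                cohort=cohort, train_patients=ids[:3], test_patients=ids[3:]
            )
        )
        b = run_benchmark(
            tiny_config(
                cohort=cohort, train_patients=ids[:3], test_patients=[ids[3]]
            )
        )
        assert a["selection"] == b["selection"]

    def test_overlapping_split_hard_fails(self):
        ids = [f"sub-{i + 1:03d}" for i in range(4)]
        with pytest.raises(ValueError):
            run_benchmark(
                tiny_config(train_patients=ids[:2], test_patients=ids[1:])
            )


class TestCli:
    def test_generate_and_qc(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "cohort:\n  n_patients: 2\n  recording_duration: 200.0\n"
            "  seizure_duration_range: [20.0, 30.0]\n  seed: 1\n"
        )
        out = tmp_path / "data"
        res = runner.invoke(
            cli_main, ["generate", "--config", str(cfg), "--out", str(out)]
        )
        assert res.exit_code == 0, res.output
        assert len(list(out.glob("*.edf"))) == 2
        qc_out = tmp_path / "qc.csv"
        res = runner.invoke(cli_main, ["qc", str(out), "--out", str(qc_out)])
        assert res.exit_code == 0, res.output
        qc = pd.read_csv(qc_out)
        assert len(qc) == 2 and not qc["excluded"].any()

    def test_preprocess_detect_postprocess_evaluate(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "cohort:\n  n_patients: 1\n  recording_duration: 200.0\n"
            "  seizure_duration_range: [20.0, 30.0]\n  seed: 2\n"
        )
        out = tmp_path / "data"
        runner.invoke(
            cli_main, ["generate", "--config", str(cfg), "--out", str(out)]
        )
        edf = sorted(out.glob("*.edf"))[0]
        pre = tmp_path / "pre.csv"
        res = runner.invoke(
            cli_main, ["preprocess", str(edf), "--out", str(pre)]
        )
        assert res.exit_code == 0, res.output
        assert len(pd.read_csv(pre)) == 200 * 8
        events = tmp_path / "events.csv"
        res = runner.invoke(
            cli_main, ["detect", "mp", str(edf), "--out", str(events)]
        )
        assert res.exit_code == 0, res.output
        clustered = tmp_path / "clustered.csv"
        res = runner.invoke(
            cli_main,
            ["postprocess", str(events), "--delta-t", "30", "--out", str(clustered)],
        )
        assert res.exit_code == 0, res.output
        metrics = tmp_path / "metrics.csv"
        res = runner.invoke(
            cli_main,
            [
                "evaluate",
                str(clustered),
                str(out / "annotations.tsv"),
                "--mode",
                "sdw",
                "--hours",
                str(200 / 3600),
                "--out",
                str(metrics),
            ],
        )
        assert res.exit_code == 0, res.output
        df = pd.read_csv(metrics)
        assert {"sensitivity", "far", "hms"} <= set(df.columns)
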