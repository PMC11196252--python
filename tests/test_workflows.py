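"""End-to-end workflow and CLI behaviour."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from voltities.cli import main
from voltities.workflows import PipelineConfig, PipelineConfigError, run_workflow


def write_config(tmp_path, **overrides):
    payload = {
        "workflow": "synth",
        "outdir": "out",
        "seed": 3,
    }
    payload.update(overrides)
    path = tmp_path / "config.yaml"
    path.write_text(yaml.safe_dump(payload))
    return path


@pytest.fixture
def synth_bundle(tmp_path):
    """A synthetic study bundle generated into tmp_path/data."""
    config = PipelineConfig(workflow="synth", outdir=tmp_path / "data", seed=3)
    run_workflow(config)
    return tmp_path / "data"


class TestConfig:
    def test_yaml_round_trip_and_relative_paths(self, tmp_path):
        (tmp_path / "part.csv").write_text("pH,half_wave_V\n")
        path = write_config(
            tmp_path, workflow="ities", inputs={"partition": "part.csv"}
        )
        config = PipelineConfig.from_yaml(path)
        assert config.inputs["partition"] == tmp_path / "part.csv"
        assert config.outdir == tmp_path / "out"

    def test_unknown_keys_and_bad_workflow_rejected(self, tmp_path):
        with pytest.raises(PipelineConfigError, match="unknown"):
            PipelineConfig.from_yaml(write_config(tmp_path, bogus=1))
        with pytest.raises(PipelineConfigError, match="workflow"):
            PipelineConfig(workflow="nope", outdir=tmp_path)

    def test_area_validation(self, tmp_path):
        with pytest.raises(PipelineConfigError, match="electrode_area"):
            PipelineConfig(workflow="gce", outdir=tmp_path, electrode_area=-1.0)

    def test_hash_depends_on_seed(self, tmp_path):
        a = PipelineConfig(workflow="synth", outdir=tmp_path, seed=1)
        b = PipelineConfig(workflow="synth", outdir=tmp_path, seed=2)
        assert a.config_hash() != b.config_hash()


class TestSynthWorkflow:
    def test_bundle_files_and_determinism(self, tmp_path):
        config = PipelineConfig(workflow="synth", outdir=tmp_path / "a", seed=3)
        run_workflow(config)
        first = (tmp_path / "a" / "report.json").read_bytes()
        for name in ("partition.csv", "calibration_forward.csv",
                     "cv_trace.csv", "standard_additions.csv", "truth.json"):
            assert (tmp_path / "a" / name).exists()
        run_workflow(
            PipelineConfig(workflow="synth", outdir=tmp_path / "b", seed=3)
        )
        assert (tmp_path / "b" / "report.json").read_bytes() == first

    def test_run_log_records_version_seed_and_hash(self, tmp_path):
        config = PipelineConfig(workflow="synth", outdir=tmp_path / "a", seed=9)
        run_workflow(config)
        log = (tmp_path / "a" / "run.log").read_text()
        assert "seed=9" in log
        assert config.config_hash() in log


class TestItiesWorkflow:
    def test_end_to_end_recovery_from_synthetic_bundle(self, tmp_path, synth_bundle):
        config = PipelineConfig(
            workflow="ities",
            outdir=tmp_path / "ities_out",
            inputs={
                "partition": synth_bundle / "partition.csv",
                "calibration_forward": synth_bundle / "calibration_forward.csv",
                "calibration_backward": synth_bundle / "calibration_backward.csv",
            },
            electrode_area=1.331,
            seed=3,
        )
        report = run_workflow(config)
        truth = json.loads((synth_bundle / "truth.json").read_text())
        kd = report["results"]["K_D"]
        assert kd == pytest.approx(truth["partition"]["K_D"], rel=0.15)
        phi0 = report["results"]["phi0_V"]
        assert phi0 == pytest.approx(truth["partition"]["phi0_V"], abs=0.003)
        fwd = report["results"]["calibrations"]["forward"]
        assert fwd["slope_A_per_M"] == pytest.approx(
            truth["calibration_forward"]["sensitivity_A_per_M"], rel=0.02
        )
        assert (tmp_path / "ities_out" / "calibration_table.csv").exists()
        assert (tmp_path / "ities_out" / "physchem_constants.csv").exists()
        constants = report["results"]["constants"]
        assert constants["logP_water_org"] == pytest.approx(-2.08, abs=0.08)

    def test_missing_input_is_config_error(self, tmp_path):
        config = PipelineConfig(
            workflow="ities", outdir=tmp_path / "o", inputs={}
        )
        with pytest.raises(PipelineConfigError, match="partition"):
            run_workflow(config)


class TestGceWorkflow:
    def test_calibration_and_regime(self, tmp_path, synth_bundle):
        rates = np.array([0.01, 0.05, 0.1, 0.2, 0.5])
        srs = tmp_path / "srs.csv"
        srs.write_text(
            "scan_rate_Vs,Ip_uA\n"
            + "\n".join(f"{v},{3.0 * v ** 0.40}" for v in rates)
            + "\n"
        )
        config = PipelineConfig(
            workflow="gce",
            outdir=tmp_path / "gce_out",
            inputs={
                "calibration": synth_bundle / "calibration_gce.csv",
                "scan_rate_study": srs,
            },
            electrode_area=0.071,
            seed=3,
        )
        report = run_workflow(config)
        diag = report["results"]["scan_rate_diagnostic"]
        assert diag["regime"] == "mixed"
        assert diag["loglog_slope"] == pytest.approx(0.40, abs=1e-6)
        cal = report["results"]["calibrations"]["gce"]
        assert cal["slope_A_per_M"] == pytest.approx(0.0300, rel=0.05)
        assert cal["normalized_slope_A_per_M_cm2"] == pytest.approx(
            cal["slope_A_per_M"] / 0.071
        )


class TestMilkWorkflow:
    def test_blank_subtraction_then_standard_addition(self, tmp_path, synth_bundle):
        from voltities import generate_swv_trace, subtract_blank, write_voltammogram

        blank = generate_swv_trace(0.25, 0.0, 0.03, baseline=(5.0, 0.4))
        sample = generate_swv_trace(0.25, 2.0, 0.03, baseline=(5.0, 0.4))
        write_voltammogram(sample, tmp_path / "sample.csv")
        write_voltammogram(blank, tmp_path / "blank.csv")
        config = PipelineConfig(
            workflow="milk",
            outdir=tmp_path / "milk_out",
            inputs={
                "standard_additions": synth_bundle / "standard_additions.csv",
                "sample_trace": tmp_path / "sample.csv",
                "blank_trace": tmp_path / "blank.csv",
            },
            seed=3,
        )
        report = run_workflow(config)
        truth = json.loads((synth_bundle / "truth.json").read_text())
        sa = report["results"]["standard_addition"]
        assert sa["concentration_uM"] == pytest.approx(
            truth["standard_additions"]["true_concentration_uM"], rel=0.10
        )
        peak = report["results"]["blank_subtracted_peak"]
        assert peak["peak_current_uA"] == pytest.approx(2.0, rel=0.02)


class TestCli:
    def test_synth_then_ities_via_cli(self, tmp_path):
        runner = CliRunner()
        config = write_config(tmp_path, workflow="synth", outdir="data")
        result = runner.invoke(main, ["synth", "--config", str(config)])
        assert result.exit_code == 0, result.output

        ities_cfg = tmp_path / "ities.yaml"
        ities_cfg.write_text(yaml.safe_dump({
            "workflow": "ities",
            "outdir": "ities_out",
            "inputs": {
                "partition": "data/partition.csv",
                "calibration_forward": "data/calibration_forward.csv",
            },
            "seed": 3,
        }))
        result = runner.invoke(main, ["ities", "--config", str(ities_cfg)])
        assert result.exit_code == 0, result.output
        report = json.loads((tmp_path / "ities_out" / "report.json").read_text())
        assert report["results"]["K_D"] == pytest.approx(600.0, rel=0.3)

    def test_missing_input_exits_with_config_code(self, tmp_path):
        runner = CliRunner()
        config = write_config(tmp_path, workflow="ities", inputs={})
        result = runner.invoke(main, ["ities", "--config", str(config)])
        assert result.exit_code == 2

    def test_missing_file_exits_with_io_code(self, tmp_path):
        runner = CliRunner()
        config = write_config(
            tmp_path, workflow="ities",
            inputs={"partition": "nope.csv", "calibration_forward": "nope2.csv"},
        )
        result = runner.invoke(main, ["ities", "--config", str(config)])
        assert result.exit_code == 3

    def test_report_command_builds_comparison_table(self, tmp_path):
        runner = CliRunner()
        config = write_config(tmp_path, workflow="synth", outdir="data")
        assert runner.invoke(main, ["synth", "--config", str(config)]).exit_code == 0
        ities_cfg = tmp_path / "i.yaml"
        ities_cfg.write_text(yaml.safe_dump({
            "workflow": "ities", "outdir": "iout",
            "inputs": {"partition": "data/partition.csv",
                       "calibration_forward": "data/calibration_forward.csv",
                       "calibration_backward": "data/calibration_backward.csv"},
            "seed": 3,
        }))
        assert runner.invoke(main, ["ities", "--config", str(ities_cfg)]).exit_code == 0
        result = runner.invoke(main, [
            "report", str(tmp_path / "iout" / "report.json"),
            "--out", str(tmp_path / "table"),
        ])
        assert result.exit_code == 0, result.output
        table = (tmp_path / "table" / "calibration_table.csv").read_text()
        assert "LOD (uM)" in table and "report:forward" in table
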