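"""Schedule I/O, configuration validation, the pipeline, and CLI exit codes."""

import json

import click
import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from hpburden.cli import EXIT_NUMERICAL, EXIT_VALIDATION, _exit_codes, main
from hpburden.interface_io import (
    NumericalError,
    RunConfig,
    ValidationError,
    read_params_csv,
    read_schedule,
    run_pipeline,
    write_params_csv,
    write_schedule,
)
from hpburden.hp_mortality import REFERENCE_PARAMS
from hpburden.synthetic_data import SyntheticConfig, simulate_schedule


class TestReadSchedule:
    def test_two_row_file(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("age,qx\n45,0.05\n46,0.06\n")
        sched = read_schedule(path)
        assert len(sched) == 2
        assert sched.qx == pytest.approx([0.05, 0.06])

    def test_rejects_q_out_of_range_naming_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("age,qx\n45,0.05\n46,1.2\n")
        with pytest.raises(ValidationError, match="row 1.*1.2"):
            read_schedule(path)

    def test_rejects_duplicate_ages(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("age,qx\n45,0.05\n45,0.06\n")
        with pytest.raises(ValidationError, match="duplicate age"):
            read_schedule(path)

    def test_rejects_deaths_exceeding_exposure(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("age,qx,exposure,deaths\n45,0.5,10,11\n")
        with pytest.raises(ValidationError, match="exceed exposure"):
            read_schedule(path)

    def test_normalizes_row_order(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("age,qx\n46,0.06\n45,0.05\n")
        sched = read_schedule(path)
        assert list(sched.ages) == [45.0, 46.0]

    def test_round_trip_identity(self, tmp_path):
        sched = simulate_schedule(SyntheticConfig(grid="annual", seed=9))
        path = write_schedule(sched, tmp_path / "sim.csv", config_hash="abc123")
        assert path.read_text().startswith("# hpburden-config: abc123")
        back = read_schedule(path)
        assert np.array_equal(back.ages, sched.ages)
        assert np.array_equal(back.qx, sched.qx)
        assert np.array_equal(back.deaths, sched.deaths)

    def test_params_round_trip(self, tmp_path):
        path = write_params_csv(REFERENCE_PARAMS, tmp_path / "p.csv")
        assert read_params_csv(path) == REFERENCE_PARAMS


class TestRunConfig:
    def test_defaults_reproduce_reference_setup(self):
        config = RunConfig()
        assert config.l0 == 160_000.0
        assert config.economics.gdp_per_capita == 17_347.0
        assert config.economics.retirement_age == 67.0
        assert config.mode == "replication"
        assert config.propagation_step == 0.25

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text(yaml.safe_dump({"retirment_age": 65}))
        with pytest.raises(ValidationError, match="unknown config key"):
            RunConfig.from_yaml(path)

    def test_day_denominated_delay(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text(yaml.safe_dump({"delay_days": 365.25}))
        config = RunConfig.from_yaml(path)
        assert config.scenario.delay == pytest.approx(1.0)

    def test_conflicting_delay_units_rejected(self):
        with pytest.raises(ValidationError, match="not both"):
            RunConfig(delay_years=1.0, delay_days=10.0)

    def test_hash_is_stable_and_sensitive(self):
        assert RunConfig().config_hash() == RunConfig().config_hash()
        assert RunConfig().config_hash() != RunConfig(seed=1).config_hash()


class TestRunPipeline:
    @pytest.fixture()
    def fast_config(self, tmp_path):
        def make(**overrides):
            defaults = dict(
                output_dir=str(tmp_path / overrides.pop("name", "out")),
                grid="annual",
                noise_free=True,
                seed=0,
            )
            defaults.update(overrides)
            return RunConfig(**defaults)

        return make

    def test_artifacts_and_conservation(self, fast_config):
        result = run_pipeline(fast_config())
        for key in ("schedule", "fit", "params", "life_table", "burden_json", "burden_csv", "log"):
            assert result.artifacts[key].exists(), key
        t = result.trajectory
        assert t.lx[-1] + t.dx.sum() == pytest.approx(t.initial_cohort, rel=1e-9)
        payload = json.loads(result.artifacts["burden_json"].read_text())
        assert payload["config_hash"] == result.config.config_hash()
        assert payload["yll_total"] == pytest.approx(result.report.yll_total)

    def test_deterministic_burden_artifacts(self, fast_config):
        a = run_pipeline(fast_config(name="a", noise_free=False, seed=7))
        b = run_pipeline(fast_config(name="b", noise_free=False, seed=7))
        csv_a = a.artifacts["burden_csv"].read_text().splitlines()[1:]
        csv_b = b.artifacts["burden_csv"].read_text().splitlines()[1:]
        assert csv_a == csv_b  # identical numbers under the same seed

    def test_sweep_csv_shape(self, fast_config):
        result = run_pipeline(fast_config(delays=[0.0, 0.5, 1.0, 2.0]))
        lines = result.artifacts["sweep"].read_text().splitlines()
        assert lines[0].startswith("# hpburden-config:")
        rows = lines[2:]  # comment + header
        assert len(rows) == 4 * 3  # 4 delays x 3 metrics
        for metric in ("yll_total", "yppll_total", "cpl_total"):
            assert sum(metric in r for r in rows) == 4

    def test_reads_external_schedule(self, fast_config, tmp_path):
        sched = simulate_schedule(SyntheticConfig(grid="annual", noise_free=True))
        path = write_schedule(sched, tmp_path / "ext.csv")
        result = run_pipeline(fast_config(name="ext", schedule_csv=str(path)))
        assert result.fit.params.H == pytest.approx(REFERENCE_PARAMS.H, rel=1e-3)

    def test_missing_schedule_is_validation_error(self):
        with pytest.raises(ValidationError, match="does not exist"):
            RunConfig(schedule_csv="no/such/file.csv")


class TestCLI:
    def test_simulate_fit_roundtrip(self, tmp_path):
        runner = CliRunner()
        sched_path = tmp_path / "sched.csv"
        out = runner.invoke(main, ["simulate", "--out", str(sched_path), "--grid", "annual",
                                   "--noise-free"])
        assert out.exit_code == 0, out.output
        fit_path = tmp_path / "fit.json"
        out = runner.invoke(main, ["fit", str(sched_path), "--out", str(fit_path)])
        assert out.exit_code == 0, out.output
        payload = json.loads(fit_path.read_text())
        assert payload["params"]["H"] == pytest.approx(REFERENCE_PARAMS.H, rel=1e-3)

    def test_lifetable_and_burden(self, tmp_path):
        runner = CliRunner()
        lt_path = tmp_path / "lt.csv"
        out = runner.invoke(main, ["lifetable", "--out", str(lt_path)])
        assert out.exit_code == 0, out.output
        burden_path = tmp_path / "burden.json"
        out = runner.invoke(main, ["burden", str(lt_path), "--out", str(burden_path)])
        assert out.exit_code == 0, out.output
        payload = json.loads(burden_path.read_text())
        assert payload["cpl_total"] == pytest.approx(
            payload["yppll_total"] * payload["economics"]["gdp_per_capita"]
        )

    def test_validation_exit_code(self, tmp_path):
        runner = CliRunner()
        bad = tmp_path / "bad.csv"
        bad.write_text("age,qx\n45,1.7\n")
        out = runner.invoke(main, ["fit", str(bad), "--out", str(tmp_path / "f.json")])
        assert out.exit_code == EXIT_VALIDATION

    def test_missing_file_exit_code(self, tmp_path):
        runner = CliRunner()
        out = runner.invoke(main, ["fit", str(tmp_path / "nope.csv"),
                                   "--out", str(tmp_path / "f.json")])
        assert out.exit_code == EXIT_VALIDATION

    def test_numerical_exit_code_mapping(self):
        @click.command()
        @_exit_codes
        def boom():
            raise NumericalError("diverged")

        out = CliRunner().invoke(boom, [])
        assert out.exit_code == EXIT_NUMERICAL

    def test_run_subcommand(self, tmp_path):
        config = {"output_dir": str(tmp_path / "run_out"), "grid": "annual",
                  "noise_free": True}
        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump(config))
        out = CliRunner().invoke(main, ["run", str(path)])
        assert out.exit_code == 0, out.output
        assert (tmp_path / "run_out" / "burden.json").exists()
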