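"""End-to-end scenario runs, sensitivity sweeps, report files, CLI."""

import json

import pandas as pd
import pytest
from click.testing import CliRunner

from appcap.cli import main
from appcap.report import run_scenario, sensitivity_sweep, write_report


@pytest.fixture(scope="module")
def report(config_module, synth_files):
    return run_scenario(
        config_module, synth_files.register_path, synth_files.appointments_path
    )


@pytest.fixture(scope="module")
def config_module():
    from appcap import default_scenario

    return default_scenario()


class TestRunScenario:
    def test_headline_capacity_figures(self, report):
        assert (report.per_pcn["diverted_per_app"] == 1665).all()
        assert (report.per_pcn["group_participants"] == 48).all()
        assert (report.per_pcn["group_person_sessions"] == 384).all()

    def test_population_shares_partition_area(self, report):
        assert report.aggregate["population_share"] == pytest.approx(1.0)

    def test_aggregate_is_columnwise_sum(self, report):
        for col in ("in_scope_population", "mh_appointments_year", "freed_low"):
            assert report.aggregate[col] == pytest.approx(
                report.per_pcn[col].sum(), rel=1e-6
            )

    def test_parameter_recovery_within_2_percent(self, report, synth_files):
        """Known generator parameters are recovered through the pipeline."""
        from appcap.synth import SynthSpec

        spec = SynthSpec()
        for register, (_, row) in zip(synth_files.registers, report.per_pcn.iterrows()):
            adults = sum(
                p.list_size_by_age_band["15+"] for p in register.practices
            )
            assert row["in_scope_population"] == pytest.approx(
                adults * 0.40 * 0.70, rel=1e-9
            )
            expected_mh = (
                register.total_population
                * spec.per_capita_gp_appointment_rate
                * spec.gp_share_of_all_appointments
                * 0.33
            )
            assert row["mh_appointments_year"] == pytest.approx(expected_mh, rel=0.02)

    def test_determinism_identical_digests(self, config_module, synth_files):
        a = run_scenario(
            config_module, synth_files.register_path, synth_files.appointments_path
        )
        b = run_scenario(
            config_module, synth_files.register_path, synth_files.appointments_path
        )
        assert a.digest() == b.digest()

    def test_empty_register_all_zero(self, config_module, tmp_path, synth_files):
        empty = tmp_path / "empty.csv"
        empty.write_text("practice_id,pcn_id,age_band,patients\n")
        report = run_scenario(config_module, empty, synth_files.appointments_path)
        assert report.per_pcn.empty
        assert report.aggregate["in_scope_population"] == 0.0

    def test_scaled_headline_uses_n_pcns(self, report):
        assert report.scaled["diverted_appointments_all_pcns"] == 1665 * 41


class TestWriteReport:
    def test_row_and_file_accounting(self, report, tmp_path):
        paths = write_report(report, tmp_path, formats=("csv", "json"))
        assert len(paths) == 2
        frame = pd.read_csv(paths[0])
        assert len(frame) == 41 + 1  # per-PCN rows + aggregate
        assert frame.iloc[-1]["pcn_id"] == "ALL"
        payload = json.loads(paths[1].read_text())
        assert len(payload["per_pcn"]) == 41

    def test_rerun_byte_stable(self, report, tmp_path):
        first = write_report(report, tmp_path / "a")
        second = write_report(report, tmp_path / "b")
        for p1, p2 in zip(first, second):
            assert p1.read_bytes() == p2.read_bytes()


class TestSensitivitySweep:
    def test_baseline_visits_monotone(self, config_module, synth_files):
        table = sensitivity_sweep(
            config_module,
            "diversion.baseline_gp_visits_per_patient",
            [3, 4],
            synth_files.register_path,
            synth_files.appointments_path,
        )
        freed = table[table.metric == "freed_low"].sort_values("value")
        assert freed.result.is_monotonic_increasing

    def test_zero_prevalence_zeroes_in_scope(self, config_module, synth_files):
        table = sensitivity_sweep(
            config_module,
            "cascade.mh_prevalence",
            [0.0],
            synth_files.register_path,
            synth_files.appointments_path,
        )
        assert (table[table.metric == "in_scope_population"].result == 0).all()

    def test_44_weeks_same_cycle_outputs(self, config_module, synth_files):
        table = sensitivity_sweep(
            config_module,
            "annualization.weeks_per_year",
            [44, 45],
            synth_files.register_path,
            synth_files.appointments_path,
        )
        participants = table[table.metric == "group_participants_all_pcns"]
        assert participants.result.nunique() == 1  # 44 weeks already fit 3+1 cycles

    def test_unknown_parameter_path_raises(self, config_module, synth_files):
        from appcap.errors import ConfigError

        with pytest.raises(ConfigError):
            sensitivity_sweep(
                config_module,
                "cascade.nope",
                [1],
                synth_files.register_path,
                synth_files.appointments_path,
            )


class TestCLI:
    def test_run_and_templates(self, synth_files, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            main,
            [
                "run",
                "--register",
                str(synth_files.register_path),
                "--appointments",
                str(synth_files.appointments_path),
                "--out",
                str(tmp_path / "out"),
            ],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "out" / "report.csv").exists()

        listing = runner.invoke(main, ["templates", "list"])
        assert listing.exit_code == 0
        assert "standard (active):" in listing.output
        assert "brief_interventions: 28.12 h/week" in listing.output

    def test_synth_subcommand(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["synth", "--seed", "9", "--n-pcns", "2", "--out", str(tmp_path / "s")],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "s" / "manifest.json").exists()

    def test_invalid_config_exits_2(self, synth_files, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("cascade:\n  mh_prevalence: 1.5\n")
        runner = CliRunner()
        result = runner.invoke(
            main,
            [
                "run",
                "--config",
                str(bad),
                "--register",
                str(synth_files.register_path),
                "--appointments",
                str(synth_files.appointments_path),
                "--out",
                str(tmp_path / "o"),
            ],
        )
        assert result.exit_code == 2
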