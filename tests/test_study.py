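"""Reproduction path, study orchestration, and the CLI layer."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import voxdose as vd
from voxdose.cli import main as cli_main


@pytest.fixture(scope="module")
def reports():
    table, reps, summary = vd.reproduce()
    return table, reps, summary


class TestReproduction:
    """Deterministic conversion of the packaged reference S-value table
    into total organ doses (3 GBq, 64.1 h effective half-life)."""

    def test_published_dose_range_endpoints(self, reports):
        _, reps, summary = reports
        r = summary["organ_dose_ranges_gy"]
        assert round(r["female"]["liver"]["max"]) == 84
        assert round(r["female"]["liver"]["min"]) == 54
        assert round(r["male"]["liver"]["max"]) == 64
        assert round(r["female"]["lung"]["max"], 2) == 0.34
        assert round(r["female"]["lung"]["min"], 3) == 0.005
        assert round(r["male"]["lung"]["max"], 2) == 0.26
        assert round(r["male"]["lung"]["min"], 3) == 0.004
        assert round(r["female"]["kidney"]["max"], 2) == 0.48
        assert round(r["male"]["kidney"]["max"], 2) == 0.43
        assert round(r["male"]["kidney"]["min"], 2) == 0.05
        marrow_max = max(r[s]["marrow"]["max"] for s in ("female", "male"))
        assert marrow_max < 0.1

    def test_dominance_at_least_100_every_row(self, reports):
        table, _, summary = reports
        assert summary["dominance"]["all_at_least_100"]
        assert summary["dominance"]["min_ratio"] == pytest.approx(122.6, abs=0.05)

    def test_reproduction_writes_outputs(self, tmp_path):
        vd.reproduce(tmp_path)
        doses = pd.read_csv(tmp_path / "doses.csv")
        assert len(doses) == 13 * 4
        summary = json.loads((tmp_path / "summary.json").read_text())
        assert "organ_dose_ranges_gy" in summary

    def test_reference_table_shape(self):
        table = vd.load_reference_svalues()
        assert len(table.records) == 13
        sexes = [r.sex for r in table.records]
        assert sexes.count("female") == 6 and sexes.count("male") == 7
        for r in table.records:
            assert set(r.s_values) == {"liver", "lung", "kidney", "marrow"}


class TestConvertTable:
    def test_empty_table_gives_empty_reports(self, caplog):
        empty = vd.SValueTable(records=[])
        reports = vd.convert_table(empty)
        assert reports == []

    def test_malformed_csv_names_row_and_column(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("sex,bmi,liver,lung\nfemale,20.0,not-a-number,1e-7\n")
        with pytest.raises(vd.ConfigurationError, match="row 1.*liver"):
            vd.read_svalue_csv(bad)

    def test_csv_without_targets_rejected(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("sex,bmi\nfemale,20.0\n")
        with pytest.raises(vd.ConfigurationError):
            vd.read_svalue_csv(bad)


class TestRunStudy:
    @pytest.fixture(scope="class")
    def small_config(self, tmp_path_factory):
        return vd.RunConfig(
            presets=[("female", 18.6), ("male", 35.8)],
            n_histories=20_000,
            seed=7,
            out_dir=str(tmp_path_factory.mktemp("study")),
        )

    def test_study_produces_full_table_and_manifest(self, small_config):
        table, reports, manifest = vd.run_study(small_config)
        assert len(table.records) == 2
        for rec in table.records:
            assert set(rec.s_values) == {"liver", "lung", "kidney", "marrow"}
            cross = [v for k, v in rec.s_values.items() if k != "liver"]
            assert rec.s_values["liver"] > max(cross)
        assert all(e["status"] == "ok" for e in manifest.per_phantom)
        assert all("seed" in e for e in manifest.per_phantom)

    def test_rerun_is_bit_identical(self, small_config):
        t1, _, _ = vd.run_study(small_config)
        t2, _, _ = vd.run_study(small_config)
        assert t1.to_frame().equals(t2.to_frame())

    def test_both_engines_cross_check_recorded(self):
        config = vd.RunConfig(
            presets=[("female", 22.1)], n_histories=10_000, seed=5, engine="both"
        )
        table, _, manifest = vd.run_study(config)
        entry = manifest.per_phantom[0]
        assert "kernel_engine_svalues" in entry
        s_mc = table.records[0].s_values["liver"]
        s_k = entry["kernel_engine_svalues"]["liver"]
        assert s_k == pytest.approx(s_mc, rel=0.10)

    def test_invalid_config_rejected(self):
        with pytest.raises(vd.ConfigurationError):
            vd.RunConfig(presets=[])
        with pytest.raises(vd.ConfigurationError):
            vd.RunConfig(n_histories=50)

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = tmp_path / "run.yaml"
        cfg.write_text(
            "phantoms:\n  - {sex: female, bmi: 18.6}\n"
            "sampling: {n_histories: 5000, seed: 3}\n"
            "admin: {activity_mbq: 3000, half_life_h: 64.1, convention: simple}\n"
        )
        config = vd.RunConfig.from_yaml(cfg)
        assert config.presets == [("female", 18.6)]
        assert config.n_histories == 5000 and config.seed == 3


class TestCli:
    def test_reproduce_command(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["reproduce", "--out", str(tmp_path)])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "doses.csv").exists()
        assert "organ_dose_ranges_gy" in result.output

    def test_convert_command(self, tmp_path):
        csv = tmp_path / "s.csv"
        csv.write_text("sex,bmi,liver,lung\nfemale,20.0,1.0e-4,1.0e-7\n")
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["convert", "--svalues", str(csv), "--activity-mbq", "3000",
             "--half-life-h", "64.1", "--convention", "simple"],
        )
        assert result.exit_code == 0, result.output
        assert "liver" in result.output

    def test_list_presets(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["phantom", "--list-presets"])
        assert result.exit_code == 0
        assert len(result.output.strip().splitlines()) == 13
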