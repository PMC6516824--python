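"""Configuration, runners and the CLI: validation, outputs, reproducibility."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner
from pydantic import ValidationError

from condkin import FIXTURES, RunConfig, load_config, make_fixtures, run_simulation, run_sweep
from condkin.cli import main


class TestConfig:
    def test_defaults_fill_and_resolve(self):
        cfg = RunConfig(gamma=3.0)
        d = cfg.resolved_dict()
        assert d["schema_version"] == "1"
        assert d["k_plus"] == 0.5
        assert cfg.resolved_gamma() == 3.0

    def test_gamma_derived_from_delta_chi(self):
        cfg = RunConfig(delta_chi=float(np.log(3.0)), phi_I=1.0, phi_II=0.0)
        assert cfg.resolved_gamma() == pytest.approx(3.0)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValidationError):
            RunConfig(gamma=3.0, not_a_key=1)

    def test_missing_partitioning_rejected(self):
        with pytest.raises(ValidationError, match="gamma"):
            RunConfig()

    def test_bad_geometry_names_field(self):
        with pytest.raises(ValidationError, match="phi_bar"):
            RunConfig(gamma=2.0, phi_bar=1.5)


class TestRunners:
    def test_fig3_run_enriches_compartment(self, tmp_path):
        cfg = RunConfig.model_validate({**FIXTURES["fig3"], "t_end": 50.0})
        summary = run_simulation(cfg, tmp_path)
        assert summary["converged"]
        assert summary["ca_I_inf"] > summary["ca_II_inf"]
        assert summary["mass_residual_max"] < 1e-6
        df = pd.read_csv(tmp_path / "trajectory.csv")
        assert list(df.columns) == [
            "time", "c_a_I", "M_a_I", "M_m_I", "c_a_II", "M_a_II", "M_m_II", "mass_residual",
        ]
        assert np.all(np.isfinite(df.to_numpy()))

    def test_gamma_one_has_zero_relative_concentration(self, tmp_path):
        cfg = RunConfig.model_validate(
            {**FIXTURES["fig3"], "gamma": 1.0, "model": "quasi-equilibrium", "t_end": 60.0}
        )
        summary = run_simulation(cfg, tmp_path)
        hom = RunConfig.model_validate(
            {k: v for k, v in FIXTURES["fig3"].items() if k != "model"}
            | {"model": "homogeneous", "t_end": 60.0}
        )
        s2 = run_simulation(hom, tmp_path / "hom")
        C = (summary["ca_tot"] - s2["ca_inf"]) / s2["ca_inf"]
        assert C == pytest.approx(0.0, abs=1e-6)

    def test_round_trip_resolved_config_reproduces_output(self, tmp_path):
        cfg = RunConfig.model_validate({**FIXTURES["fig3"], "t_end": 30.0})
        run_simulation(cfg, tmp_path / "a")
        cfg2 = load_config(tmp_path / "a" / "resolved_config.json")
        run_simulation(cfg2, tmp_path / "b")
        assert (tmp_path / "a" / "trajectory.csv").read_text() == (
            tmp_path / "b" / "trajectory.csv"
        ).read_text()

    def test_sweep_runner_writes_long_csv(self, tmp_path):
        cfg = RunConfig.model_validate(
            {
                **FIXTURES["fig5a"],
                "sweep_phi_bar": [0.2, 0.6],
                "sweep_gamma": [2.0, 8.0],
            }
        )
        meta = run_sweep(cfg, tmp_path)
        df = pd.read_csv(tmp_path / "sweep.csv")
        assert len(df) == 4
        assert df["converged"].all()
        assert (df["C"] < 0).all()  # n2=0: compartments always reduce the pool
        assert meta["schema_version"] == "1"


class TestFixtures:
    def test_fixture_names_stable(self):
        assert set(FIXTURES) == {
            "fig3",
            "fig3e_primary",
            "fig3e_secondary",
            "fig5a",
            "fig5bc",
            "boundary",
        }

    def test_all_fixtures_validate_and_write(self, tmp_path):
        paths = make_fixtures(tmp_path)
        assert set(paths) == set(FIXTURES)
        for p in paths.values():
            cfg = load_config(p)  # re-validates
            assert cfg.resolved_gamma() > 0


class TestCli:
    def test_validate_prints_resolved_config(self, tmp_path):
        path = tmp_path / "c.json"
        path.write_text(json.dumps({"gamma": 3.0, "n2": 0}))
        res = CliRunner().invoke(main, ["validate", "--config", str(path)])
        assert res.exit_code == 0
        assert json.loads(res.output)["n2"] == 0

    def test_malformed_config_fails_with_error_record(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"gamma": 3.0, "bogus": 1}))
        res = CliRunner().invoke(main, ["validate", "--config", str(path)])
        assert res.exit_code == 1
        err = json.loads(res.output.strip().splitlines()[-1])
        assert "bogus" in err["message"]

    def test_simulate_subcommand_end_to_end(self, tmp_path):
        res = CliRunner().invoke(
            main,
            [
                "simulate",
                "--set", "gamma=3.0",
                "--set", "t_end=50.0",
                "--out", str(tmp_path / "run"),
            ],
        )
        assert res.exit_code == 0, res.output
        summary = json.loads(res.output)
        assert summary["converged"] and summary["epsilon"] > 1.0

    def test_predict_subcommand(self):
        res = CliRunner().invoke(
            main, ["predict", "--gamma", "3", "--vi-frac", "0.5", "--n1", "2", "--n2", "0"]
        )
        assert res.exit_code == 0
        out = json.loads(res.output)
        assert out["regime"] == "large-compartment-optimal"

    def test_fixtures_subcommand(self, tmp_path):
        res = CliRunner().invoke(main, ["fixtures", "--out", str(tmp_path)])
        assert res.exit_code == 0
        assert (tmp_path / "fig5bc.json").exists()
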