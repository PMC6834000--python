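"""Fixture generation, reports and the command-line interface."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import tvcoupling as tv
from tvcoupling.cli import main as cli_main
from tvcoupling.fixtures import FIXTURES, make_fixture


def test_fixture_names_cover_study_conditions():
    assert set(FIXTURES) == {"fig2", "fig3a", "fig3b", "fig3c", "fig3d",
                             "frozen_locked", "frozen_drift", "noisy_inference"}


def test_unknown_fixture_rejected(tmp_path):
    with pytest.raises(KeyError):
        make_fixture("nope", outdir=tmp_path)


def test_fixture_determinism(tmp_path):
    a = make_fixture("noisy_inference", seed=3, outdir=tmp_path / "a",
                     duration=2.0)
    b = make_fixture("noisy_inference", seed=3, outdir=tmp_path / "b",
                     duration=2.0)
    assert a["csv"].read_bytes() == b["csv"].read_bytes()
    c = make_fixture("noisy_inference", seed=4, outdir=tmp_path / "c",
                     duration=2.0)
    assert a["csv"].read_bytes() != c["csv"].read_bytes()


def test_fixture_row_count_matches_duration(tmp_path):
    # duration/h + 1 rows; scaled-down stand-in for the 5e6-row default
    paths = make_fixture("fig2", outdir=tmp_path, duration=5.0, h=0.01)
    frame = pd.read_csv(paths["csv"])
    assert len(frame) == 501
    assert list(frame.columns) == ["t", "psi_unwrapped", "psi_wrapped", "f",
                                   "phi_shift", "c1", "c2"]
    cfg = json.loads(paths["config"].read_text())
    assert cfg["schedule"]["alpha"] == pytest.approx(1.55 / math.sqrt(2))
    amp = np.hypot(frame.c1, frame.c2)
    assert np.allclose(amp, 1.55, atol=1e-9)


def test_fig3d_has_zero_slow_rate(tmp_path):
    paths = make_fixture("fig3d", outdir=tmp_path, duration=2.0, h=0.01)
    cfg = json.loads(paths["config"].read_text())
    assert cfg["schedule"]["eps"] == 0.0
    assert cfg["schedule"]["kfast"] == 1.0
    assert cfg["schedule"]["alpha"] == pytest.approx(1.176 / math.sqrt(2))


def test_noisy_inference_fixture_columns(tmp_path):
    paths = make_fixture("noisy_inference", outdir=tmp_path, duration=2.0)
    frame = pd.read_csv(paths["csv"])
    assert list(frame.columns) == ["t", "phi1", "phi2"]


def test_cli_simulate_analyze_report_roundtrip(tmp_path):
    runner = CliRunner()
    out = tmp_path / "run.csv"
    res = runner.invoke(cli_main, [
        "simulate", "--mode", "psi", "--detuning", "1.08",
        "--alpha", str(1.55 / math.sqrt(2)), "--eps", "0.01",
        "--kfast", "100", "--period", "1000", "--t1", "490", "--t2", "990",
        "--duration", "1200", "--step", "0.01", "--out", str(out)])
    assert res.exit_code == 0, res.output
    assert out.exists() and out.with_suffix(".json").exists()
    sidecar = json.loads(out.with_suffix(".json").read_text())
    assert sidecar["Omega"] == 1.08

    seg_out = tmp_path / "seg.json"
    res = runner.invoke(cli_main, ["analyze", "--track", str(out),
                                   "--out", str(seg_out)])
    assert res.exit_code == 0, res.output
    seg = json.loads(seg_out.read_text())
    labels = [i["label"] for i in seg["intervals"]]
    assert "locked" in labels and "slipping" in labels

    res = runner.invoke(cli_main, ["report", "--track", str(out)])
    assert res.exit_code == 0, res.output
    assert "locked" in res.output


def test_cli_simulate_config_file(tmp_path):
    import yaml

    cfg = tmp_path / "cfg.yaml"
    cfg.write_text(yaml.safe_dump({
        "mode": "psi", "Omega": 1.08, "alpha": 1.55 / math.sqrt(2),
        "rate": 0.0, "duration": 10.0, "h": 0.01}))
    out = tmp_path / "frozen.csv"
    res = CliRunner().invoke(cli_main, ["simulate", "--config", str(cfg),
                                        "--out", str(out)])
    assert res.exit_code == 0, res.output
    frame = pd.read_csv(out)
    assert frame.psi_unwrapped.iloc[-1] == pytest.approx(
        math.asin(1.08 / 1.55), abs=1e-3)


def test_cli_infer(tmp_path):
    paths = make_fixture("noisy_inference", outdir=tmp_path, duration=60.0)
    out = tmp_path / "windows.csv"
    res = CliRunner().invoke(cli_main, [
        "infer", "--track", str(paths["csv"]), "--window", "25",
        "--stride", "12.5", "--order", "1", "--out", str(out)])
    assert res.exit_code == 0, res.output
    frame = pd.read_csv(out)
    assert {"window_center", "omega2_hat", "eps", "rho"} <= set(frame.columns)
    summary = json.loads(out.with_suffix(".summary.json").read_text())
    assert summary["n_windows"] == len(frame)


def test_cli_bounds(tmp_path):
    res = CliRunner().invoke(cli_main, [
        "bounds", "--detuning", "1.08", "--alpha", str(1.55 / math.sqrt(2)),
        "--k1", "100"])
    assert res.exit_code == 0, res.output
    payload = json.loads(res.output)
    assert payload["kappa0"] == pytest.approx(2 * math.pi * 1.55 / 100)


def test_cli_fixture_and_tabulate(tmp_path):
    res = CliRunner().invoke(cli_main, [
        "fixture", "frozen_drift", "--outdir", str(tmp_path),
        "--duration", "5", "--step", "0.01"])
    assert res.exit_code == 0, res.output
    out = tmp_path / "mod.csv"
    res = CliRunner().invoke(cli_main, [
        "tabulate", "--alpha", "1.0", "--eps", "0.01", "--kfast", "100",
        "--period", "1000", "--t1", "490", "--t2", "990",
        "--duration", "1000", "--step", "1.0", "--out", str(out)])
    assert res.exit_code == 0, res.output
    frame = pd.read_csv(out)
    assert frame.f.iloc[750] == pytest.approx(100.0)
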