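"""Tests for scenario runners, exports and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from circentrain import ModelParams, ScenarioSpec, export_report, run_jetlag, run_shiftwork
from circentrain.scenarios import ScenarioReport, trajectory_frame, validate_summary
from circentrain.cli import main as cli_main


def test_scenario_spec_validation():
    with pytest.raises(ValueError):
        ScenarioSpec(kind="weekend")
    with pytest.raises(ValueError):
        ScenarioSpec(strategy="teleport")
    with pytest.raises(ValueError):
        ScenarioSpec(I_shift=-5.0)
    spec = ScenarioSpec(kind="shiftwork", shift_start_clock=20.0, shift_end_clock=8.0)
    assert spec.shift_span == (-12.0, 0.0)
    spec = ScenarioSpec(kind="shiftwork", shift_start_clock=22.0, shift_end_clock=8.0)
    assert spec.shift_span == (-10.0, 0.0)


def test_clock_bookkeeping(cycle3):
    """t=0 of the cycle is 6 am: the published 10 am / 10 pm initial states
    are Y_REF(4) and Y_REF(16)."""
    y4 = cycle3.state(4.0)
    assert y4[1] == pytest.approx(0.0815, abs=5e-3)
    assert y4[3] == pytest.approx(0.1984, abs=5e-3)
    y16 = cycle3.state(16.0)
    assert y16[3] == pytest.approx(0.5854, abs=5e-3)


def test_jetlag_trivial(params, cycle3):
    rep = run_jetlag(ScenarioSpec(kind="jetlag", strategy="open-loop",
                                  delta_shift=0.0, dt=0.02), params, cycle3)
    assert rep.t_f == pytest.approx(0.0, abs=1e-6)


def test_shiftwork_open_loop_matches_published(params, cycle3):
    rep = run_shiftwork(ScenarioSpec(kind="shiftwork", strategy="open-loop",
                                     I_shift=0.0), params, cycle3)
    assert rep.t_f == pytest.approx(3.46, rel=0.02)


def test_scenarios_are_deterministic(params, cycle3):
    spec = ScenarioSpec(kind="shiftwork", strategy="open-loop", I_shift=100.0, dt=0.01)
    r1 = run_shiftwork(spec, params, cycle3)
    r2 = run_shiftwork(spec, params, cycle3)
    assert r1.t_f == r2.t_f
    assert np.array_equal(r1.trajectory.Y, r2.trajectory.Y)


def test_export_report_roundtrip(params, cycle3, tmp_path):
    rep = run_shiftwork(ScenarioSpec(kind="shiftwork", strategy="open-loop",
                                     I_shift=0.0, dt=0.02), params, cycle3)
    paths = export_report(rep, tmp_path / "out")
    df = pd.read_csv(paths["trajectory"])
    assert len(df) == len(rep.trajectory)
    # sleepiness column equals H - A_c x recomputed from the same rows
    np.testing.assert_allclose(df.B.values, df.H.values - params.A_c * df.x.values,
                               atol=1e-9)
    # beta changes only at recorded switch events
    sched = pd.read_csv(paths["schedule"])
    assert (df.beta.diff().fillna(0) != 0).sum() == len(sched)
    summary = json.loads(paths["summary"].read_text())
    validate_summary(summary)
    assert summary["t_f_h"] == pytest.approx(rep.t_f)


def test_export_empty_trajectory(params, tmp_path):
    spec = ScenarioSpec(kind="jetlag", strategy="open-loop")
    rep = ScenarioReport(spec, None, None, "spontaneous", None, params, 1.0)
    frame = trajectory_frame(rep)
    assert len(frame) == 0 and "B" in frame.columns
    paths = export_report(rep, tmp_path / "empty")
    df = pd.read_csv(paths["trajectory"])
    assert len(df) == 0


def test_c_only_tuned_strategy_trivial(params, cycle3):
    """Light-only optimization + tuned sleep rule on an already-entrained
    traveler finishes immediately."""
    spec = ScenarioSpec(kind="jetlag", strategy="C-only-tuned", delta_shift=0.0,
                        I_max=10000.0, dt=0.02, bins_h=1.0, resolution=1.0,
                        max_inner=15)
    rep = run_jetlag(spec, params, cycle3)
    assert rep.t_f == pytest.approx(0.0, abs=0.5)


def test_transfer_strategy_entrains_full_model(params, cycle3):
    """A reduced-model (S+C2) optimum transferred to the full model entrains
    it, with the sleepiness-guarded schedule and supplement phase."""
    spec = ScenarioSpec(kind="jetlag", strategy="transfer-S+C2", delta_shift=2.0,
                        I_max=10000.0, dt=0.02, bins_h=1.0, resolution=1.0,
                        max_inner=15)
    rep = run_jetlag(spec, params, cycle3)
    assert rep.t_f is not None
    assert rep.extras["t_f_reduced"] > 0
    # transferred lights are bang-off in {0, I_max} during the reduced phase
    n_red = sum(1 for e in rep.light.edges if e <= rep.extras["t_f_reduced"]) - 1
    lux = np.round(np.unique(rep.light.levels[:max(n_red, 1)]), 4)
    assert set(lux) <= {0.0, 1000.0, 10000.0}


def test_cli_reference_and_scenario(tmp_path):
    runner = CliRunner()
    cache = str(tmp_path / "cache")
    res = runner.invoke(cli_main, ["--cache-dir", cache, "reference", "build"])
    assert res.exit_code == 0, res.output
    assert "entrained cycle" in res.output
    out_dir = str(tmp_path / "scen")
    res = runner.invoke(cli_main, [
        "--cache-dir", cache, "scenario", "shiftwork", "open-loop",
        "--i-shift", "0", "--dt", "0.02", "--out", out_dir,
    ])
    assert res.exit_code == 0, res.output
    assert "t_f = 3.4" in res.output
    assert (tmp_path / "scen" / "summary.json").exists()
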