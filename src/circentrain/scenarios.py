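"""Jet-lag and shift-work scenario runners with CSV/JSON exports.

Clock bookkeeping: time 0 of the reference cycle is 6 am.  A jet-lag
entrainment that starts at 7 am local time uses ``delta_init = 1`` and the
traveler's initial state is the reference state of the origin time zone,
``y(0) = Y_REF(delta_shift + delta_init)``.  A night shift ending at 8 am
uses ``delta_init = 2``; the shift itself (e.g. 8 pm - 8 am, simulation time
-12 to 0) is spent forced awake under the working light ``I_shift``, and the
entrainment time is counted from the end of the shift.

All scenario runs are deterministic -- there is no randomness anywhere in
the models or the optimizers; identical configurations produce identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .control import (
    OptimResult,
    TerminalSpec,
    apply_transferred,
    first_crossing,
    minimize_time_controllable,
    minimize_time_spontaneous,
    open_loop_entrain,
    optimize_process_C_only,
    transfer_reduced_solution,
)
from .models import (
    HybridTrajectory,
    LightSignal,
    TunedSleepRule,
    TwoProcessState,
    integrate_hybrid,
)
from .params import ModelParams
from .reference import ReferenceCycle, compute_entrained_cycle, estimate_prc

__all__ = ["ScenarioSpec", "ScenarioReport", "run_jetlag", "run_shiftwork",
           "export_report", "SUMMARY_SCHEMA", "validate_summary"]

STRATEGIES = (
    "open-loop",
    "min-time-spontaneous",
    "min-time-controllable",
    "min-time-with-shift-light",
    "C-only-tuned",
    "feedback",
    "transfer-S+C1",
    "transfer-S+C2",
)


@dataclass
class ScenarioSpec:
    """Descriptor of one entrainment experiment (fully deterministic)."""

    kind: str = "jetlag"               # jetlag | shiftwork
    strategy: str = "open-loop"
    delta_shift: float = 0.0           # h, origin-vs-destination offset (jet lag)
    delta_init: float = 1.0            # h past 6 am at entrainment start
    shift_start_clock: float = 20.0    # night-shift start, o'clock (shift work)
    shift_end_clock: float = 8.0       # night-shift end, o'clock
    I_shift: float = 0.0               # lux during the shift
    I_max: float = 10000.0             # lux bound for optimized light
    variant: str = "S+C3"
    tol: float = 0.01
    dt: float = 0.005
    bins_h: float = 0.1
    resolution: float = 0.02
    max_inner: int = 40
    horizon_cap: float = 1000.0

    def __post_init__(self) -> None:
        if self.kind not in ("jetlag", "shiftwork"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; options: {STRATEGIES}")
        if self.I_shift < 0 or self.I_max < 0:
            raise ValueError("light intensities must be non-negative")

    @property
    def shift_span(self) -> tuple[float, float]:
        """Night-shift window in simulation time, ending at t = 0."""
        dur = (self.shift_end_clock - self.shift_start_clock) % 24.0
        return (-dur, 0.0)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class ScenarioReport:
    spec: ScenarioSpec
    t_f: float | None
    trajectory: HybridTrajectory | None
    schedule: list[tuple[float, int]] | str
    light: LightSignal | None
    params: ModelParams
    delta_init: float
    optim: OptimResult | None = None
    extras: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "schema": "circentrain.scenario_summary/1",
            "kind": self.spec.kind,
            "strategy": self.spec.strategy,
            "t_f_h": self.t_f,
            "entrained": self.t_f is not None,
            "delta_shift_h": self.spec.delta_shift,
            "delta_init_h": self.delta_init,
            "I_shift_lux": self.spec.I_shift,
            "I_max_lux": self.spec.I_max,
            "variant": self.spec.variant,
            "tol": self.spec.tol,
            "config_hash": self.spec.config_hash(),
        }


SUMMARY_SCHEMA = {
    "schema": str, "kind": str, "strategy": str, "t_f_h": (float, int, type(None)),
    "entrained": bool, "delta_shift_h": (float, int), "delta_init_h": (float, int),
    "I_shift_lux": (float, int), "I_max_lux": (float, int), "variant": str,
    "tol": (float, int), "config_hash": str,
}


def validate_summary(summary: dict) -> None:
    """Check a scenario summary against the shipped schema (raises on error)."""
    for key, typ in SUMMARY_SCHEMA.items():
        if key not in summary:
            raise ValueError(f"summary missing key {key!r}")
        if not isinstance(summary[key], typ):
            raise ValueError(f"summary key {key!r} has wrong type {type(summary[key])}")


def _dispatch(
    spec: ScenarioSpec,
    state0: TwoProcessState,
    delta_init: float,
    cycle: ReferenceCycle,
    params: ModelParams,
    tspec: TerminalSpec,
    *,
    t_start: float = 0.0,
    fixed_pre_light: LightSignal | None = None,
    controller=None,
) -> ScenarioReport:
    kw = dict(bins_h=spec.bins_h, dt=spec.dt, resolution=spec.resolution,
              max_inner=spec.max_inner, horizon_cap=spec.horizon_cap)
    if spec.strategy == "open-loop":
        ol = open_loop_entrain(state0, delta_init, cycle, tspec, params,
                               t_start=t_start, pre_light=fixed_pre_light,
                               horizon_cap=spec.horizon_cap, dt=spec.dt)
        return ScenarioReport(spec, ol.t_f, ol.trajectory, "spontaneous", None,
                              params, delta_init)
    if spec.strategy == "min-time-spontaneous":
        res = minimize_time_spontaneous(state0, delta_init, cycle, spec.I_max, tspec,
                                        params, t_start=t_start,
                                        fixed_pre_light=fixed_pre_light, **kw)
        return ScenarioReport(spec, res.t_f, res.trajectory, res.schedule, res.light,
                              params, delta_init, optim=res)
    if spec.strategy in ("min-time-controllable", "min-time-with-shift-light"):
        res = minimize_time_controllable(
            state0, delta_init, cycle, spec.I_max, tspec, params,
            t_start=t_start, fixed_pre_light=fixed_pre_light,
            shift_light_free=(spec.strategy == "min-time-with-shift-light"), **kw)
        return ScenarioReport(spec, res.t_f, res.trajectory, res.schedule, res.light,
                              params, delta_init, optim=res)
    if spec.strategy == "C-only-tuned":
        if t_start < 0:
            raise ValueError("C-only-tuned strategy is defined for jet-lag scenarios")
        cycle_C = compute_entrained_cycle("C3", params, photoperiod=(1.5, 16.0))
        y0_C = state0.y[:3].copy()
        res_C = optimize_process_C_only(
            TwoProcessState("C3", y0_C), delta_init, spec.I_max, params,
            cycle_C=cycle_C, tol=spec.tol, **kw)
        light = res_C.light
        horizon = float(light.edges[-1])
        supplement = LightSignal.constant(0.0, horizon, horizon + 48.0, I_max=spec.I_max)
        light_full = light.concat(supplement)
        traj = integrate_hybrid(state0, light_full, TunedSleepRule(light_full),
                                (0.0, horizon + 48.0), params, dt=spec.dt)
        t_f = first_crossing(traj, delta_init, cycle, tspec)
        return ScenarioReport(spec, t_f, traj,
                              [(t, b) for t, _o, b, _g in traj.switch_events],
                              light_full, params, delta_init, optim=res_C,
                              extras={"t_f_C_only": res_C.t_f})
    if spec.strategy in ("transfer-S+C1", "transfer-S+C2"):
        variant_from = spec.strategy.split("-", 1)[1]
        prc = estimate_prc(params) if variant_from == "S+C1" else None
        red_cycle = compute_entrained_cycle(variant_from, params, prc=prc)
        red_spec = TerminalSpec(variant_from, spec.tol)
        y0_red = red_cycle.state(spec.delta_shift + delta_init)
        st_red = TwoProcessState(variant_from, y0_red,
                                 beta=red_cycle.beta_at(spec.delta_shift + delta_init))
        res_red = minimize_time_controllable(st_red, delta_init, red_cycle, spec.I_max,
                                             red_spec, params, prc=prc, **kw)
        light, policy = transfer_reduced_solution(res_red, variant_from, spec.I_max,
                                                  params, delta_init=delta_init)
        out = apply_transferred(state0, light, policy, delta_init, cycle, tspec,
                                params, dt=spec.dt, horizon_cap=spec.horizon_cap)
        return ScenarioReport(spec, out.t_f, out.trajectory,
                              [(t, b) for t, _o, b, _g in out.trajectory.switch_events],
                              light, params, delta_init, optim=res_red,
                              extras={"t_f_reduced": res_red.t_f})
    if spec.strategy == "feedback":
        from .feedback import simulate_feedback

        if controller is None:
            raise ValueError("feedback strategy requires a trained controller")
        t_f, traj = simulate_feedback(state0, delta_init, cycle, controller, tspec,
                                      params, dt=spec.dt, horizon_cap=spec.horizon_cap)
        return ScenarioReport(spec, t_f, traj,
                              [(t, b) for t, _o, b, _g in traj.switch_events],
                              None, params, delta_init)
    raise ValueError(spec.strategy)  # pragma: no cover


def run_jetlag(
    spec: ScenarioSpec,
    params: ModelParams | None = None,
    cycle: ReferenceCycle | None = None,
    controller=None,
) -> ScenarioReport:
    """Entrain a traveler: ``y(0) = y_ref(delta_shift)`` against the
    destination reference ``y_ref(t) = Y_REF(t + delta_init)``."""
    params = params or ModelParams()
    cycle = cycle or compute_entrained_cycle(spec.variant, params)
    tspec = TerminalSpec(spec.variant, spec.tol)
    arg = spec.delta_shift + spec.delta_init
    state0 = TwoProcessState(spec.variant, cycle.state(arg), beta=cycle.beta_at(arg))
    return _dispatch(spec, state0, spec.delta_init, cycle, params, tspec,
                     controller=controller)


def run_shiftwork(
    spec: ScenarioSpec,
    params: ModelParams | None = None,
    cycle: ReferenceCycle | None = None,
    controller=None,
) -> ScenarioReport:
    """Entrain a night-shift worker after a forced-awake shift.

    The worker starts the shift on the reference schedule
    (``y(t_start) = y_ref(t_start)``), stays awake under ``I_shift`` until
    8 am (t = 0), then entrains by the chosen strategy; the reported ``t_f``
    excludes the shift itself.  With strategy ``min-time-with-shift-light``
    the shift-window light becomes part of the decision, bounded by I_max.
    """
    params = params or ModelParams()
    cycle = cycle or compute_entrained_cycle(spec.variant, params)
    delta_init = (spec.shift_end_clock - 6.0) % 24.0
    tspec = TerminalSpec(spec.variant, spec.tol)
    t_start, _ = spec.shift_span
    if t_start >= 0.0:
        raise ValueError("night-shift window must have positive duration")
    arg = t_start + delta_init
    state0 = TwoProcessState(spec.variant, cycle.state(arg), beta=0)
    pre = LightSignal.constant(spec.I_shift, t_start, 0.0,
                               I_max=max(spec.I_shift, spec.I_max, 1.0))
    return _dispatch(spec, state0, delta_init, cycle, params, tspec,
                     t_start=t_start, fixed_pre_light=pre, controller=controller)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def trajectory_frame(report: ScenarioReport) -> pd.DataFrame:
    """Tabulate a trajectory: times, clock time, states, sleepiness, light, drive."""
    cols = ["t_h", "clock_time", "n", "x", "x_c", "H", "theta", "B", "beta", "I_lux", "u"]
    traj = report.trajectory
    if traj is None or len(traj) == 0:
        return pd.DataFrame(columns=cols)
    p = report.params
    t = traj.times
    clock = np.mod(6.0 + t + report.delta_init, 24.0)
    if traj.variant == "S+C3":
        n, x, xc, H = (traj.Y[:, j] for j in range(4))
    elif traj.variant == "S+C2":
        x, xc, H = (traj.Y[:, j] for j in range(3))
        n = np.full_like(x, np.nan)
    elif traj.variant == "S+C1":
        theta_col = np.mod(traj.Y[:, 0], 2 * np.pi)
        H = traj.Y[:, 1]
        x = np.cos(theta_col)
        xc = np.full_like(x, np.nan)
        n = np.full_like(x, np.nan)
    else:
        n, x, xc = (traj.Y[:, j] for j in range(3))
        H = np.full_like(x, np.nan)
    if traj.variant == "S+C1":
        theta = theta_col
    else:
        theta = np.mod(np.arctan2(-xc, x), 2 * np.pi)
    B = traj.B(p) if traj.variant in ("S+C3", "S+C2", "S+C1") else np.full_like(x, np.nan)
    return pd.DataFrame({
        "t_h": t, "clock_time": clock, "n": n, "x": x, "x_c": xc, "H": H,
        "theta": theta, "B": B, "beta": traj.beta.astype(int), "I_lux": traj.I,
        "u": traj.u(p),
    })


def export_report(report: ScenarioReport, out_dir: str | Path, *, plot: bool = False) -> dict:
    """Write trajectory.csv, schedule.csv, summary.json (and optionally a
    PNG overview plot) into ``out_dir``; returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    df = trajectory_frame(report)
    paths["trajectory"] = out / "trajectory.csv"
    df.to_csv(paths["trajectory"], index=False)

    sched_rows = []
    if report.trajectory is not None:
        for (t, old, new, tag) in report.trajectory.switch_events:
            sched_rows.append({"t_h": t, "old_beta": old, "new_beta": new, "trigger": tag})
    paths["schedule"] = out / "schedule.csv"
    pd.DataFrame(sched_rows, columns=["t_h", "old_beta", "new_beta", "trigger"]).to_csv(
        paths["schedule"], index=False)

    if report.light is not None:
        rows = [{"time_start_h": report.light.edges[i], "time_end_h": report.light.edges[i + 1],
                 "lux": report.light.levels[i]} for i in range(len(report.light.levels))]
        paths["light"] = out / "light.csv"
        pd.DataFrame(rows).to_csv(paths["light"], index=False)

    summary = report.summary()
    validate_summary(summary)
    paths["summary"] = out / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=1))

    if plot and report.trajectory is not None and len(df):
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, axes = plt.subplots(2, 1, sharex=True, figsize=(9, 6))
            axes[0].plot(df.t_h, df.x, label="x")
            axes[0].plot(df.t_h, df.H, label="H")
            axes[0].legend(loc="upper right")
            axes[0].set_ylabel("state")
            axes[1].plot(df.t_h, df.B, label="B")
            axes[1].fill_between(df.t_h, 0, 1, where=df.beta == 1, alpha=0.2,
                                 color="k", label="sleep")
            axes[1].fill_between(df.t_h, 0, 1, where=df.I_lux > 0, alpha=0.15,
                                 color="r", label="light on")
            axes[1].set_xlabel("t (h)")
            axes[1].set_ylabel("sleepiness")
            axes[1].legend(loc="upper right")
            fig.tight_layout()
            paths["plot"] = out / "overview.png"
            fig.savefig(paths["plot"], dpi=110)
            plt.close(fig)
        except ImportError:  # pragma: no cover - plotting is optional
            pass
    return paths
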