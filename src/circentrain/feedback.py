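"""Nearest-neighbor feedback controller learned from optimal trajectories.

Real-time entrainment cannot rerun the functional gradient descent at every
instant.  Instead, a feedback policy is distilled from a library of optimal
minimum-time solutions: sample each optimal trajectory densely, keep the
measured state (circadian phase ``theta``, homeostat ``H``, reference phase
``theta_ref``) together with the optimal action at that instant, and answer
closed-loop queries with the action of the nearest training record.

While awake the policy returns the light intensity and a countdown
``gamma_sleep`` to the next scheduled sleep onset; while asleep it returns a
countdown ``gamma_wake`` to the next wake.  The retinal state ``n`` is
ignored (Process L is a fast transient).  Phases enter the metric as
``(cos, sin)`` pairs so the distance respects circularity; ``H`` is already
in [0, 1] and is left unscaled.  k = 1 with ties broken toward the lowest
record index.

In closed loop the controller is re-queried every ``control_period`` (default
0.1 h); a fresh query overrides the previous countdown, which makes the
policy Markov in the measured state.  Switches commanded by an expiring
countdown remain subject to the sleepiness-bound safety overrides, so the
closed-loop schedule can never violate the bound constraints.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .control import (
    GuardedSchedule,
    OptimResult,
    TerminalSpec,
    first_crossing,
    minimize_time_controllable,
    terminal_residual,
)
from .models import (
    HybridTrajectory,
    LightSignal,
    TwoProcessState,
    integrate_hybrid,
)
from .params import ModelParams
from .reference import ReferenceCycle, phase_of

__all__ = [
    "TrainingDataset",
    "FeedbackController",
    "build_training_set",
    "controller_step",
    "simulate_feedback",
]

TWO_PI = 2.0 * math.pi


def _features(theta, H, theta_ref) -> np.ndarray:
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    H = np.atleast_1d(np.asarray(H, dtype=float))
    theta_ref = np.atleast_1d(np.asarray(theta_ref, dtype=float))
    return np.column_stack([
        np.cos(theta), np.sin(theta), H, np.cos(theta_ref), np.sin(theta_ref)
    ])


@dataclass
class TrainingDataset:
    """Sampled optimal trajectories split into wake and sleep records.

    Wake records carry the optimal light and the sleep countdown; sleep
    records carry the wake countdown.  ``case_id`` ties each record to the
    time-shift case it came from.
    """

    wake: pd.DataFrame   # theta, H, theta_ref, I, gamma_sleep, case_id
    sleep: pd.DataFrame  # theta, H, theta_ref, gamma_wake, case_id
    I_max: float
    delta_init: float
    sample_dt: float = 0.01
    case_t_f: dict[int, float] = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        w = self.wake.copy()
        w["beta"] = 0
        s = self.sleep.copy()
        s["beta"] = 1
        df = pd.concat([w, s], ignore_index=True)
        df.to_csv(path, index=False)
        manifest = {
            "schema": "circentrain.training_set/1",
            "I_max": self.I_max,
            "delta_init": self.delta_init,
            "sample_dt": self.sample_dt,
            "case_t_f": {str(k): v for k, v in self.case_t_f.items()},
            "n_wake": int(len(self.wake)),
            "n_sleep": int(len(self.sleep)),
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrainingDataset":
        path = Path(path)
        df = pd.read_csv(path)
        man = json.loads(path.with_suffix(".json").read_text())
        wake = df[df.beta == 0].drop(columns=["beta", "gamma_wake"], errors="ignore")
        sleep = df[df.beta == 1].drop(columns=["beta", "I", "gamma_sleep"], errors="ignore")
        return cls(
            wake=wake.reset_index(drop=True), sleep=sleep.reset_index(drop=True),
            I_max=man["I_max"], delta_init=man["delta_init"],
            sample_dt=man["sample_dt"],
            case_t_f={int(k): v for k, v in man["case_t_f"].items()},
        )


def _trajectory_records(
    traj: HybridTrajectory,
    schedule: list[tuple[float, int]],
    t_f: float,
    delta_init: float,
    cycle: ReferenceCycle,
    params: ModelParams,
    sample_dt: float,
    case_id: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    ts = np.round(np.arange(0.0, t_f + sample_dt / 2, sample_dt), 9)
    Y = np.column_stack([np.interp(ts, traj.times, traj.Y[:, j])
                         for j in range(traj.Y.shape[1])])
    beta = np.array([traj.beta_at(t) for t in ts], dtype=int)
    I = np.array([traj.I[min(np.searchsorted(traj.times, t + 1e-9) - 1,
                             len(traj.I) - 1)] for t in ts])
    if traj.variant == "S+C3":
        theta = np.mod(np.arctan2(-Y[:, 2], Y[:, 1]), TWO_PI)
        H = Y[:, 3]
    elif traj.variant == "S+C2":
        theta = np.mod(np.arctan2(-Y[:, 1], Y[:, 0]), TWO_PI)
        H = Y[:, 2]
    else:
        theta = np.mod(Y[:, 0], TWO_PI)
        H = Y[:, 1]
    theta_ref = cycle.phase(ts + delta_init)

    # countdowns to the next switch; past the last one, continue with the
    # entrained reference pattern (the subject is entrained at t_f)
    onset, wake_clock = cycle.sleep_window()
    future = list(schedule)
    last = t_f
    for d in range(3):
        future.append((onset - delta_init + 24.0 * math.ceil((last + delta_init - onset) / 24.0) + 24.0 * d, 1))
        future.append((wake_clock - delta_init + 24.0 * math.ceil((last + delta_init - wake_clock) / 24.0) + 24.0 * d, 0))
    future.sort()
    sleep_times = np.array([t for t, b in future if b == 1])
    wake_times = np.array([t for t, b in future if b == 0])

    def next_after(times, t):
        i = np.searchsorted(times, t + 1e-9)
        return times[i] if i < len(times) else t + 24.0

    g_sleep = np.array([next_after(sleep_times, t) - t for t in ts])
    g_wake = np.array([next_after(wake_times, t) - t for t in ts])

    base = pd.DataFrame({
        "theta": theta, "H": H, "theta_ref": theta_ref, "case_id": case_id,
    })
    wake_df = base[beta == 0].copy()
    wake_df["I"] = I[beta == 0]
    wake_df["gamma_sleep"] = g_sleep[beta == 0]
    sleep_df = base[beta == 1].copy()
    sleep_df["gamma_wake"] = g_wake[beta == 1]
    return wake_df.reset_index(drop=True), sleep_df.reset_index(drop=True)


def build_training_set(
    I_max: float,
    cases: list[int] | None = None,
    delta_init: float = 1.0,
    params: ModelParams | None = None,
    *,
    cycle: ReferenceCycle | None = None,
    spec: TerminalSpec | None = None,
    sample_dt: float = 0.01,
    optimizer_kwargs: dict | None = None,
    results: dict[int, OptimResult] | None = None,
) -> TrainingDataset:
    """Run the controllable-sleep optimizer over time-shift cases and sample
    the optimal trajectories into a training set.

    ``cases`` defaults to all shifts 1..23 h; pass a subset for smaller
    studies.  Precomputed ``results`` (case -> OptimResult) are reused
    instead of re-optimizing.  Failed cases are skipped with a warning
    recorded on the dataset manifest.
    """
    from .reference import compute_entrained_cycle

    params = params or ModelParams()
    cycle = cycle or compute_entrained_cycle("S+C3", params)
    spec = spec or TerminalSpec("S+C3", 0.01)
    cases = list(cases) if cases is not None else list(range(1, 24))
    kw = dict(bins_h=0.5, dt=0.02, resolution=1.0, max_inner=25)
    kw.update(optimizer_kwargs or {})

    wake_parts, sleep_parts = [], []
    case_t_f: dict[int, float] = {}
    for shift in cases:
        res = None if results is None else results.get(shift)
        if res is None:
            st = TwoProcessState("S+C3", cycle.state(shift + delta_init),
                                 beta=cycle.beta_at(shift + delta_init))
            res = minimize_time_controllable(st, delta_init, cycle, I_max, spec,
                                             params, **kw)
        if res.trajectory is None or not res.converged:
            continue
        schedule = [] if isinstance(res.schedule, str) else list(res.schedule)
        w, s = _trajectory_records(res.trajectory, schedule, res.t_f, delta_init,
                                   cycle, params, sample_dt, case_id=shift)
        wake_parts.append(w)
        sleep_parts.append(s)
        case_t_f[shift] = res.t_f
    if not wake_parts:
        raise RuntimeError("no optimization case produced a usable trajectory")
    return TrainingDataset(
        wake=pd.concat(wake_parts, ignore_index=True),
        sleep=pd.concat(sleep_parts, ignore_index=True),
        I_max=I_max, delta_init=delta_init, sample_dt=sample_dt,
        case_t_f=case_t_f,
    )


class FeedbackController:
    """1-nearest-neighbor policy over the wake and sleep training records."""

    def __init__(self, dataset: TrainingDataset):
        if len(dataset.wake) == 0 or len(dataset.sleep) == 0:
            raise ValueError("training dataset must contain wake and sleep records")
        self.dataset = dataset
        self._wake_tree = cKDTree(_features(dataset.wake.theta.values,
                                            dataset.wake.H.values,
                                            dataset.wake.theta_ref.values))
        self._sleep_tree = cKDTree(_features(dataset.sleep.theta.values,
                                             dataset.sleep.H.values,
                                             dataset.sleep.theta_ref.values))
        self.I_max = dataset.I_max

    def _lookup(self, tree: cKDTree, q: np.ndarray) -> int:
        d, i = tree.query(q, k=2)
        d, i = np.atleast_1d(d[0] if np.ndim(d) > 1 else d), np.atleast_1d(i[0] if np.ndim(i) > 1 else i)
        if len(d) > 1 and abs(d[1] - d[0]) <= 1e-12:
            return int(min(i[0], i[1]))
        return int(i[0])

    def query_wake(self, theta: float, H: float, theta_ref: float) -> tuple[float, float]:
        """(light lux, hours until scheduled sleep onset)."""
        j = self._lookup(self._wake_tree, _features(theta, H, theta_ref))
        row = self.dataset.wake.iloc[j]
        return float(row.I), float(row.gamma_sleep)

    def query_sleep(self, theta: float, H: float, theta_ref: float) -> float:
        """Hours until the scheduled wake."""
        j = self._lookup(self._sleep_tree, _features(theta, H, theta_ref))
        return float(self.dataset.sleep.iloc[j].gamma_wake)


def controller_step(theta: float, H: float, theta_ref: float, beta: int,
                    controller: FeedbackController):
    """One policy evaluation: ``(I, gamma_sleep)`` when awake, else
    ``gamma_wake``."""
    if beta == 0:
        return controller.query_wake(theta, H, theta_ref)
    return controller.query_sleep(theta, H, theta_ref)


def simulate_feedback(
    state0: TwoProcessState,
    delta_init: float,
    cycle: ReferenceCycle,
    controller: FeedbackController,
    spec: TerminalSpec,
    params: ModelParams | None = None,
    *,
    control_period: float = 0.1,
    dt: float = 0.005,
    horizon_cap: float = 600.0,
) -> tuple[float | None, HybridTrajectory]:
    """Closed-loop simulation under the nearest-neighbor policy.

    The controller is re-queried every ``control_period`` hours; a switch
    commanded by an expiring countdown is applied through the guarded
    schedule, so the sleepiness bound constraints stay enforced.  Returns the
    first terminal-condition crossing (None if the horizon cap is exceeded)
    and the full trajectory.
    """
    params = params or ModelParams()
    if state0.variant != "S+C3":
        raise ValueError("feedback simulation runs on the full S+C3 model")
    t = 0.0
    y = state0.y.copy()
    beta = int(state0.beta)
    times = [t]
    Ys = [y.copy()]
    betas = [beta]
    I_rec = [0.0]
    events: list[tuple[float, int, int, str]] = []

    while t < horizon_cap:
        theta = phase_of(y[1], y[2])
        theta_ref = float(cycle.phase(t + delta_init))
        if beta == 0:
            I_cmd, gamma = controller.query_wake(theta, y[3], theta_ref)
            I_cmd = min(I_cmd, controller.I_max)
        else:
            I_cmd, gamma = 0.0, controller.query_sleep(theta, y[3], theta_ref)
        t_next = t + control_period
        switches = []
        if gamma < control_period:
            switches.append((t + max(gamma, 0.0), 0 if beta else 1))
        light = LightSignal.constant(I_cmd, t, t_next + 1.0, I_max=max(controller.I_max, 1.0))
        pol = GuardedSchedule(switches)
        seg = integrate_hybrid(TwoProcessState("S+C3", y, beta=beta), light, pol,
                               (t, t_next), params, dt=dt)
        times.extend(seg.times[1:])
        Ys.extend(seg.Y[1:])
        betas.extend(seg.beta[1:])
        I_rec.extend(seg.I[1:])
        events.extend(seg.switch_events)
        y = seg.Y[-1].copy()
        beta = int(seg.beta[-1])
        t = float(seg.times[-1])
        if terminal_residual(y, t, delta_init, cycle, spec) <= 0.0:
            break

    traj = HybridTrajectory("S+C3", np.array(times), np.array(Ys),
                            np.array(betas, dtype=np.int8), np.array(I_rec), events)
    t_f = first_crossing(traj, delta_init, cycle, spec)
    return t_f, traj
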