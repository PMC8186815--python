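"""Minimum-time entrainment by adjoint-based projected gradient descent.

The entrainment problem: drive the two-process state to the moving reference
``y_ref(t) = Y_REF(t + delta_init)`` until the terminal condition

    || y_cmp(t_f) - y_ref_cmp(t_f) ||_2^2  <=  tol

holds, where the compared components are ``[x, x_c, H]`` for S+C3/S+C2
(``n`` is ignored -- its time scale is minutes) and ``[theta, H]`` (angular
difference wrapped) for S+C1.  Three strategies are implemented:

* **open-loop** -- reference light + spontaneous sleep, first crossing time;
* **minimum time, spontaneous sleep** -- light is the only decision variable;
* **minimum time, controllable sleep** -- light plus the sleep/wake switch
  times, constrained by the sleepiness bounds
  ``H_m <= B(T_sleep) <= B1_max`` and ``L_m <= B(T_wake) <= B2_max``.

Gradients come from the adjoint (co-state) equation integrated backward along
the stored trajectory, with the standard hybrid-system jump at every
state-triggered sleep/wake switch (first-order variation of the trigger
condition ``B(y(t_s)) = threshold``); time-scheduled switches contribute a
switch-time gradient ``lambda^T (F_before - F_after)`` instead.  Light enters
the gradient only while awake: during sleep the input is decoupled and the
gradient over sleep bins is exactly zero.

The light schedule is piecewise constant on uniform bins.  Internally each
bin carries a decision variable ``s = (I/I_max)^p`` in [0, 1]; since
``alpha(I) = alpha0 (I/I0)^p`` this makes the dynamics affine in the decision
and keeps the gradient finite at darkness (d alpha / d I diverges as I -> 0
for p < 1).  Reported optima are thresholded to bang-off {0, I_max} at
I_max/2 and re-verified.

The minimum-time outer loop shrinks the horizon by geometric continuation
(a few percent per probe, halving the step after a failed probe, keeping
the [largest-infeasible, smallest-feasible] bracket until it closes to the
requested resolution), warm-starting each probe from the best feasible
solution truncated to the probe horizon.  Long problems are additionally
seeded with day-structured maximal delay/advance candidate schedules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import (
    ForcedAwake,
    HybridTrajectory,
    LightSignal,
    SleepPolicy,
    SpontaneousSleep,
    TransferSleepRule,
    TunedSleepRule,
    TwoProcessState,
    integrate_hybrid,
    reference_light_signal,
    state_names,
    steady_state_drive,
)
from .params import ModelParams
from .reference import ReferenceCycle, PRCTable

__all__ = [
    "TerminalSpec",
    "OptimResult",
    "PhasedPolicy",
    "GuardedSchedule",
    "terminal_residual",
    "residual_series",
    "first_crossing",
    "open_loop_entrain",
    "adjoint_gradient",
    "minimize_time_spontaneous",
    "minimize_time_controllable",
    "optimize_process_C_only",
    "tuned_sleep_rule",
    "transfer_reduced_solution",
    "apply_transferred",
    "drive_to_lux",
]

TWO_PI = 2.0 * math.pi
_PI12 = math.pi / 12.0


# ---------------------------------------------------------------------------
# Terminal condition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TerminalSpec:
    """Terminal entrainment condition: squared distance of the compared state
    components to the reference, minus ``tol``."""

    variant: str = "S+C3"
    tol: float = 0.01

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    @property
    def compared(self) -> tuple[int, ...]:
        names = state_names(self.variant)
        if self.variant in ("S+C3", "S+C2"):
            return tuple(names.index(k) for k in ("x", "x_c", "H"))
        if self.variant == "S+C1":
            return (0, 1)
        if self.variant == "C3":
            return tuple(names.index(k) for k in ("x", "x_c"))
        raise ValueError(self.variant)

    @property
    def wrap_component(self) -> int | None:
        return 0 if self.variant == "S+C1" else None


def _component_diff(y: np.ndarray, y_ref: np.ndarray, spec: TerminalSpec) -> np.ndarray:
    d = np.asarray(y)[..., list(spec.compared)] - np.asarray(y_ref)[..., list(spec.compared)]
    w = spec.wrap_component
    if w is not None:
        d[..., w] = np.mod(d[..., w] + math.pi, TWO_PI) - math.pi
    return d


def terminal_residual(
    state: TwoProcessState | np.ndarray,
    t: float,
    delta_init: float,
    cycle: ReferenceCycle,
    spec: TerminalSpec,
) -> float:
    """phi_f(y(t), t) = ||y_cmp - y_ref_cmp(t + delta_init)||^2 - tol."""
    y = state.y if isinstance(state, TwoProcessState) else np.asarray(state)
    y_ref = cycle.state(t + delta_init)
    d = _component_diff(y, y_ref, spec)
    return float(np.dot(d, d)) - spec.tol


def residual_series(
    traj: HybridTrajectory, delta_init: float, cycle: ReferenceCycle, spec: TerminalSpec
) -> np.ndarray:
    y_ref = cycle.state(traj.times + delta_init)
    d = _component_diff(traj.Y, y_ref, spec)
    return np.einsum("ij,ij->i", d, d) - spec.tol


def first_crossing(
    traj: HybridTrajectory,
    delta_init: float,
    cycle: ReferenceCycle,
    spec: TerminalSpec,
    t_min: float = 0.0,
) -> float | None:
    """First time >= t_min at which the terminal residual becomes <= 0,
    localized by linear interpolation between trajectory nodes."""
    res = residual_series(traj, delta_init, cycle, spec)
    mask = traj.times >= t_min - 1e-9
    idx = np.nonzero(mask & (res <= 0.0))[0]
    if len(idx) == 0:
        return None
    i = int(idx[0])
    if i == 0 or traj.times[i - 1] < t_min - 1e-9 or res[i - 1] <= 0.0:
        return float(max(traj.times[i], t_min))
    t_a, t_b = traj.times[i - 1], traj.times[i]
    r_a, r_b = res[i - 1], res[i]
    if r_b == r_a:
        return float(t_b)
    return float(t_a + (t_b - t_a) * (-r_a) / (r_b - r_a))


# ---------------------------------------------------------------------------
# Composite sleep policies used by the optimizers / scenarios
# ---------------------------------------------------------------------------

class PhasedPolicy(SleepPolicy):
    """Chain sleep policies over consecutive time windows.

    ``phases`` is ``[(t_end_1, policy_1), ..., (inf, policy_n)]``; policy_i
    governs ``t < t_end_i``.  Phase boundaries are surfaced to the integrator
    as schedule markers so the incoming policy can act immediately.
    """

    def __init__(self, phases: Sequence[tuple[float, SleepPolicy]]):
        self.phases = list(phases)
        if not math.isinf(self.phases[-1][0]):
            raise ValueError("last phase must extend to infinity")

    def reset(self, t0, beta0):
        for _, p in self.phases:
            p.reset(t0, beta0)

    def _active(self, t):
        for t_end, p in self.phases:
            if t < t_end - 1e-9:
                return t_end, p
        return self.phases[-1]

    def watches(self, t, beta, I, params):
        return self._active(t)[1].watches(t, beta, I, params)

    def immediate(self, t, beta, B, I, params):
        return self._active(t)[1].immediate(t, beta, B, I, params)

    def next_scheduled(self, t, beta):
        t_end, p = self._active(t)
        ts, b = p.next_scheduled(t, beta)
        if t_end < ts:
            return t_end, -2
        return ts, b


def GuardedSchedule(switches: Sequence[tuple[float, int]]) -> TransferSleepRule:
    """Controllable sleep schedule with the sleepiness-bound guards.

    Scheduled sleeps are deferred until ``B >= H_m`` and forced at
    ``B >= B1_max``; scheduled wakes are deferred until ``B <= B2_max`` and
    forced at ``B <= L_m``.  Realized switch times therefore always satisfy
    the bound constraints, implementing projection onto the feasible window.
    """
    return TransferSleepRule(switches, t_end=math.inf)


# ---------------------------------------------------------------------------
# Open-loop entrainment
# ---------------------------------------------------------------------------

@dataclass
class OpenLoopResult:
    t_f: float | None
    trajectory: HybridTrajectory


def open_loop_entrain(
    state0: TwoProcessState,
    delta_init: float,
    cycle: ReferenceCycle,
    spec: TerminalSpec,
    params: ModelParams | None = None,
    *,
    t_start: float = 0.0,
    t_min: float = 0.0,
    pre_light: LightSignal | None = None,
    pre_policy: SleepPolicy | None = None,
    horizon_cap: float = 1000.0,
    dt: float = 0.005,
    prc: PRCTable | None = None,
    I_on: float = 1000.0,
) -> OpenLoopResult:
    """Reference light + spontaneous sleep; return the first terminal crossing.

    An optional pre-phase (e.g. a forced-awake night shift with its own
    light) runs on ``[t_start, 0)`` before the entrainment light starts; the
    entrainment time is measured from ``t_min`` (default 0).  ``t_f`` is None
    if the horizon cap is exceeded without entraining.
    """
    params = params or ModelParams()
    policy: SleepPolicy = SpontaneousSleep()
    if t_start < 0.0:
        if pre_light is None:
            pre_light = LightSignal.constant(0.0, t_start, 0.0)
        policy = PhasedPolicy([(0.0, pre_policy or ForcedAwake()), (math.inf, policy)])
    prc_fn = None if prc is None else prc.fast()

    # integrate in chunks, stopping at the first terminal crossing
    chunk = 96.0
    t = t_start
    state = state0
    pieces: list[HybridTrajectory] = []
    t_f = None
    while t < horizon_cap - 1e-9:
        t_next = min(t + chunk, horizon_cap)
        light = reference_light_signal(min(t, 0.0), t_next, delta_init=delta_init, I_on=I_on)
        if t_start < 0.0 and t < 0.0 and pre_light is not None:
            light = pre_light.concat(
                reference_light_signal(0.0, t_next, delta_init=delta_init, I_on=I_on))
        traj = integrate_hybrid(state, light, policy, (t, t_next), params,
                                dt=dt, prc=prc_fn)
        pieces.append(traj)
        t_f = first_crossing(traj, delta_init, cycle, spec, t_min=t_min)
        if t_f is not None:
            break
        t = float(traj.times[-1])
        state = TwoProcessState(state.variant, traj.Y[-1].copy(), beta=int(traj.beta[-1]))

    if len(pieces) == 1:
        full = pieces[0]
    else:
        full = HybridTrajectory(
            variant=state0.variant,
            times=np.concatenate([pieces[0].times] + [p.times[1:] for p in pieces[1:]]),
            Y=np.concatenate([pieces[0].Y] + [p.Y[1:] for p in pieces[1:]]),
            beta=np.concatenate([pieces[0].beta] + [p.beta[1:] for p in pieces[1:]]),
            I=np.concatenate([pieces[0].I] + [p.I[1:] for p in pieces[1:]]),
            switch_events=[e for p in pieces for e in p.switch_events],
        )
    return OpenLoopResult(t_f=t_f, trajectory=full)


# ---------------------------------------------------------------------------
# Variant derivative helpers (Jacobian-transpose products etc.)
# ---------------------------------------------------------------------------

def _seg_alpha_u(variant, params, beta, I):
    """(alpha, u) applying on a constant segment."""
    if beta or I <= 0.0:
        return 0.0, 0.0
    a = params.alpha0 * (I / params.I0) ** params.p
    if variant in ("S+C3", "C3"):
        return a, math.nan  # u depends on n
    return a, params.G * params.gamma * a / (a + params.gamma)


def _rhs_vec(variant, params, beta, I, y, prc=None):
    """RHS as a numpy vector at a point (used at switch nodes)."""
    a, u_seg = _seg_alpha_u(variant, params, beta, I)
    if variant in ("S+C3", "C3"):
        n, x, xc = y[0], y[1], y[2]
        u = params.G * a * (1.0 - n)
        mod = (1.0 - 0.4 * x) * (1.0 - params.k_c * xc)
        dn = 60.0 * (a * (1.0 - n) - params.gamma * n)
        dx = _PI12 * (xc + params.mu * (x / 3.0 + (4 / 3) * x**3 - (256 / 105) * x**7) + mod * u)
        dxc = _PI12 * ((params.q * xc - params.k * x) * mod * u - params.freq_sq * x)
        if variant == "C3":
            return np.array([dn, dx, dxc])
        dH = -y[3] / params.tau_d if beta else (1.0 - y[3]) / params.tau_r
        return np.array([dn, dx, dxc, dH])
    if variant == "S+C2":
        x, xc, H = y
        mod = (1.0 - 0.4 * x) * (1.0 - params.k_c * xc)
        dx = _PI12 * (xc + params.mu * (x / 3.0 + (4 / 3) * x**3 - (256 / 105) * x**7) + mod * u_seg)
        dxc = _PI12 * ((params.q * xc - params.k * x) * mod * u_seg - params.freq_sq * x)
        dH = -H / params.tau_d if beta else (1.0 - H) / params.tau_r
        return np.array([dx, dxc, dH])
    if variant == "S+C1":
        th, H = y
        dth = params.omega0 + (prc(th) * u_seg if u_seg else 0.0)
        dH = -H / params.tau_d if beta else (1.0 - H) / params.tau_r
        return np.array([dth, dH])
    raise ValueError(variant)


def _make_adjoint_ops(variant, params, beta, I, prc=None, prc_deriv=None):
    """Return (rhs, neg_jac_T_prod, dF_ds) closures for one constant segment.

    ``dF_ds`` is the derivative of the RHS with respect to the normalized
    light decision s (alpha = alpha_at_Imax * s for the full model, drive
    u = u_max * s for the reduced models); the caller scales s-ranges.
    """
    g = params.gamma
    mu, q, k, kc, w2, G = params.mu, params.q, params.k, params.k_c, params.freq_sq, params.G
    hcoef = -1.0 / params.tau_d if beta else -1.0 / params.tau_r
    a, u_seg = _seg_alpha_u(variant, params, beta, I)
    awake_lit = (beta == 0)

    if variant in ("S+C3", "C3"):
        has_H = variant == "S+C3"

        def rhs(y):
            n, x, xc = y[0], y[1], y[2]
            u = G * a * (1.0 - n)
            mod = (1.0 - 0.4 * x) * (1.0 - kc * xc)
            out = [
                60.0 * (a * (1.0 - n) - g * n),
                _PI12 * (xc + mu * (x / 3.0 + (4 / 3) * x**3 - (256 / 105) * x**7) + mod * u),
                _PI12 * ((q * xc - k * x) * mod * u - w2 * x),
            ]
            if has_H:
                out.append(hcoef * (y[3] - (0.0 if beta else 1.0)))
            return out

        def njt(y, lam):
            n, x, xc = y[0], y[1], y[2]
            u = G * a * (1.0 - n)
            one_kcxc = 1.0 - kc * xc
            one_04x = 1.0 - 0.4 * x
            mod = one_04x * one_kcxc
            du_dn = -G * a
            Pp = mu * (1.0 / 3.0 + 4.0 * x * x - (1792.0 / 105.0) * x**6)
            A00 = -60.0 * (a + g)
            A10 = _PI12 * mod * du_dn
            A20 = _PI12 * (q * xc - k * x) * mod * du_dn
            A11 = _PI12 * (Pp - 0.4 * one_kcxc * u)
            A12 = _PI12 * (1.0 - kc * one_04x * u)
            A21 = _PI12 * (-k * mod * u - 0.4 * one_kcxc * (q * xc - k * x) * u - w2)
            A22 = _PI12 * (q * mod * u - kc * one_04x * (q * xc - k * x) * u)
            out = [
                -(A00 * lam[0] + A10 * lam[1] + A20 * lam[2]),
                -(A11 * lam[1] + A21 * lam[2]),
                -(A12 * lam[1] + A22 * lam[2]),
            ]
            if has_H:
                out.append(-hcoef * lam[3])
            return out

        if awake_lit:
            # s-derivative through alpha; alpha_max applied by caller
            def dFds(y, lam):
                n, x, xc = y[0], y[1], y[2]
                one_n = 1.0 - n
                mod = (1.0 - 0.4 * x) * (1.0 - kc * xc)
                return (
                    lam[0] * 60.0 * one_n
                    + lam[1] * _PI12 * mod * G * one_n
                    + lam[2] * _PI12 * (q * xc - k * x) * mod * G * one_n
                )
        else:
            dFds = None
        return rhs, njt, dFds

    if variant == "S+C2":
        def rhs(y):
            x, xc, H = y
            mod = (1.0 - 0.4 * x) * (1.0 - kc * xc)
            return [
                _PI12 * (xc + mu * (x / 3.0 + (4 / 3) * x**3 - (256 / 105) * x**7) + mod * u_seg),
                _PI12 * ((q * xc - k * x) * mod * u_seg - w2 * x),
                hcoef * (H - (0.0 if beta else 1.0)),
            ]

        def njt(y, lam):
            x, xc, _H = y
            one_kcxc = 1.0 - kc * xc
            one_04x = 1.0 - 0.4 * x
            mod = one_04x * one_kcxc
            Pp = mu * (1.0 / 3.0 + 4.0 * x * x - (1792.0 / 105.0) * x**6)
            A00 = _PI12 * (Pp - 0.4 * one_kcxc * u_seg)
            A01 = _PI12 * (1.0 - kc * one_04x * u_seg)
            A10 = _PI12 * (-k * mod * u_seg - 0.4 * one_kcxc * (q * xc - k * x) * u_seg - w2)
            A11 = _PI12 * (q * mod * u_seg - kc * one_04x * (q * xc - k * x) * u_seg)
            return [
                -(A00 * lam[0] + A10 * lam[1]),
                -(A01 * lam[0] + A11 * lam[1]),
                -hcoef * lam[2],
            ]

        if awake_lit:
            def dFds(y, lam):  # du/ds = u_max handled by caller
                x, xc, _H = y
                mod = (1.0 - 0.4 * x) * (1.0 - kc * xc)
                return lam[0] * _PI12 * mod + lam[1] * _PI12 * (q * xc - k * x) * mod
        else:
            dFds = None
        return rhs, njt, dFds

    if variant == "S+C1":
        w0 = params.omega0

        def rhs(y):
            th, H = y
            return [w0 + (prc(th) * u_seg if u_seg else 0.0),
                    hcoef * (H - (0.0 if beta else 1.0))]

        def njt(y, lam):
            dfd = prc_deriv(y[0]) * u_seg if u_seg else 0.0
            return [-dfd * lam[0], -hcoef * lam[1]]

        if awake_lit:
            def dFds(y, lam):
                return lam[0] * prc(y[0])
        else:
            dFds = None
        return rhs, njt, dFds

    raise ValueError(variant)


def _B_grad(variant, params, y):
    """dB/dy row vector for the switching-surface condition."""
    if variant == "S+C3":
        return np.array([0.0, -params.A_c, 0.0, 1.0])
    if variant == "S+C2":
        return np.array([-params.A_c, 0.0, 1.0])
    if variant == "S+C1":
        return np.array([params.A_c * math.sin(y[0]), 1.0])
    raise ValueError(variant)


# ---------------------------------------------------------------------------
# Adjoint gradient
# ---------------------------------------------------------------------------

@dataclass
class AdjointGradient:
    """Gradient of the terminal residual w.r.t. the normalized light decision
    per bin (``d_s``), and w.r.t. each time-scheduled switch (``d_switch``,
    keyed by realized switch time)."""

    d_s: np.ndarray
    d_switch: dict[float, float] = field(default_factory=dict)
    lambda0: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)


def adjoint_gradient(
    traj: HybridTrajectory,
    bin_edges: np.ndarray,
    delta_init: float,
    cycle: ReferenceCycle,
    spec: TerminalSpec,
    params: ModelParams,
    *,
    scheduled_times: Sequence[float] = (),
    prc: PRCTable | None = None,
    s_scale: float | None = None,
    I_max: float = 1000.0,
) -> AdjointGradient:
    """Backward co-state sweep along a stored trajectory.

    ``bin_edges`` delimit the piecewise-constant light decision bins (they
    must be breakpoints of the simulated light so no bin straddles a light
    discontinuity).  ``scheduled_times`` are the switch times to be treated
    as time-triggered decisions; all other switch events get the
    state-triggered co-state jump.  ``s_scale`` converts the s-derivative:
    alpha-at-I_max for the full model, u_max for reduced ones (computed from
    ``I_max`` when omitted).
    """
    variant = traj.variant
    t_f = float(traj.times[-1])
    y_f = traj.Y[-1]
    y_ref = cycle.state(t_f + delta_init)
    lam = np.zeros(traj.Y.shape[1])
    d = _component_diff(y_f, y_ref, spec)
    for j, comp in enumerate(spec.compared):
        lam[comp] = 2.0 * d[j]

    if s_scale is None:
        if variant in ("S+C3", "C3"):
            s_scale = params.alpha0 * (I_max / params.I0) ** params.p
        else:
            s_scale = steady_state_drive(I_max, params)[1]

    prc_fn = None if prc is None else prc.fast()
    prc_d = None
    if prc is not None:
        prc(0.0)  # build spline
        spl = prc._spline.derivative()
        prc_d = lambda th: float(spl(math.fmod(math.fmod(th, TWO_PI) + TWO_PI, TWO_PI)))

    sched = sorted(float(ts) for ts in scheduled_times)
    warnings: list[str] = []
    grad_s = np.zeros(max(len(bin_edges) - 1, 0))
    grad_sw: dict[float, float] = {}

    times, Y, beta, I_arr = traj.times, traj.Y, traj.beta, traj.I
    N = len(times)
    ops_cache: dict[tuple, tuple] = {}

    def ops_for(b, I_lev):
        key = (int(b), float(I_lev))
        if key not in ops_cache:
            ops_cache[key] = _make_adjoint_ops(variant, params, int(b), float(I_lev),
                                               prc=prc_fn, prc_deriv=prc_d)
        return ops_cache[key]

    i = N - 2
    while i >= 0:
        t_a, t_b = times[i], times[i + 1]
        h = t_b - t_a
        if h <= 1e-12:
            # switch node: interval [i] -> [i+1] is zero length
            if beta[i + 1] != beta[i]:
                y_s = Y[i + 1]
                F1 = _rhs_vec(variant, params, int(beta[i]), float(I_arr[i]), y_s, prc=prc_fn)
                F2 = _rhs_vec(variant, params, int(beta[i + 1]), float(I_arr[i + 1]), y_s, prc=prc_fn)
                is_sched = any(abs(t_b - ts) <= 5e-6 for ts in sched)
                if is_sched:
                    grad_sw[float(t_b)] = float(lam @ (F1 - F2))
                else:
                    gy = _B_grad(variant, params, y_s)
                    denom = float(gy @ F1)
                    if abs(denom) < 1e-6:
                        warnings.append(
                            f"degenerate switching surface at t={t_b:.4f} "
                            f"(dB/dt={denom:.2e}); co-state jump skipped"
                        )
                    else:
                        lam = lam - (float(lam @ (F1 - F2)) / denom) * gy
            i -= 1
            continue

        b, I_lev = int(beta[i]), float(I_arr[i])
        rhs, njt, dFds = ops_for(b, I_lev)
        y_b = tuple(Y[i + 1])
        y_a = tuple(Y[i])
        F_b = rhs(y_b)
        F_a = rhs(y_a)
        y_m = tuple(0.5 * (ya + yb) + 0.125 * h * (fa - fb)
                    for ya, yb, fa, fb in zip(y_a, y_b, F_a, F_b))
        # backward RK4 for lambda' = -A^T lambda over [t_b -> t_a]
        l0 = tuple(lam)
        k1 = njt(y_b, l0)
        l1 = tuple(v - 0.5 * h * kk for v, kk in zip(l0, k1))
        k2 = njt(y_m, l1)
        l2 = tuple(v - 0.5 * h * kk for v, kk in zip(l0, k2))
        k3 = njt(y_m, l2)
        l3 = tuple(v - h * kk for v, kk in zip(l0, k3))
        k4 = njt(y_a, l3)
        lam_a = tuple(v - (h / 6.0) * (a1 + 2.0 * (a2 + a3) + a4)
                      for v, a1, a2, a3, a4 in zip(l0, k1, k2, k3, k4))
        if dFds is not None and len(grad_s):
            mid = 0.5 * (t_a + t_b)
            kbin = int(np.searchsorted(bin_edges, mid) - 1)
            if 0 <= kbin < len(grad_s):
                grad_s[kbin] += 0.5 * h * (dFds(y_a, lam_a) + dFds(y_b, l0)) * s_scale
        lam = np.array(lam_a)
        i -= 1

    return AdjointGradient(d_s=grad_s, d_switch=grad_sw, lambda0=lam, warnings=warnings)


# ---------------------------------------------------------------------------
# Fixed-horizon descent and minimum-time outer loop
# ---------------------------------------------------------------------------

@dataclass
class OptimResult:
    """Outcome of a minimum-time optimization."""

    light: LightSignal
    schedule: list[tuple[float, int]] | str
    t_f: float
    residual: float
    iterations: int
    objective_history: list[float] = field(default_factory=list)
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)
    trajectory: HybridTrajectory | None = None

    def to_dict(self) -> dict:
        return {
            "t_f": self.t_f,
            "residual": self.residual,
            "iterations": self.iterations,
            "converged": self.converged,
            "schedule": self.schedule if isinstance(self.schedule, str) else
                        [[t, b] for t, b in self.schedule],
            "light_edges": self.light.edges.tolist(),
            "light_levels": self.light.levels.tolist(),
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if isinstance(v, (int, float, str, bool))},
        }


def _s_to_lux(variant: str, s: np.ndarray, I_max: float, params: ModelParams) -> np.ndarray:
    """Map normalized decisions s in [0,1] to lux levels."""
    s = np.clip(s, 0.0, 1.0)
    if variant in ("S+C3", "C3"):
        return I_max * s ** (1.0 / params.p)
    # reduced models: s = u/u_max; invert the steady-state drive map
    u_max = steady_state_drive(I_max, params)[1]
    u = u_max * s
    Gg = params.G * params.gamma
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(u < Gg, params.gamma * u / np.maximum(Gg - u, 1e-300), np.inf)
        I = params.I0 * (a / params.alpha0) ** (1.0 / params.p)
    return np.minimum(np.nan_to_num(I, nan=0.0, posinf=I_max), I_max)


def _lux_to_s(variant: str, I: np.ndarray, I_max: float, params: ModelParams) -> np.ndarray:
    I = np.clip(np.asarray(I, dtype=float), 0.0, I_max)
    if variant in ("S+C3", "C3"):
        return (I / I_max) ** params.p
    u_max = steady_state_drive(I_max, params)[1]
    a = params.alpha0 * (I / params.I0) ** params.p
    u = params.G * params.gamma * a / (a + params.gamma)
    return u / u_max


@dataclass
class _Problem:
    """Fixed ingredients of one entrainment optimization."""

    variant: str
    params: ModelParams
    cycle: ReferenceCycle
    spec: TerminalSpec
    delta_init: float
    state0: TwoProcessState
    I_max: float
    t_start: float = 0.0      # simulation start (< 0 when a shift precedes)
    ctrl_start: float = 0.0   # light decision bins start here
    fixed_pre_light: LightSignal | None = None  # on [t_start, ctrl_start)
    forced_awake_until: float | None = None     # beta pinned 0 on [t_start, this)
    sleep_mode: str = "spontaneous"             # or "controllable"
    bins_h: float = 0.1
    dt: float = 0.005
    prc: PRCTable | None = None

    def bin_edges(self, t_f: float) -> np.ndarray:
        n = max(1, math.ceil((t_f - self.ctrl_start) / self.bins_h - 1e-9))
        edges = self.ctrl_start + self.bins_h * np.arange(n + 1)
        edges[-1] = t_f
        if edges[-1] - edges[-2] < 1e-6:
            edges = np.delete(edges, len(edges) - 2)
        return edges

    def light_of(self, edges: np.ndarray, s: np.ndarray) -> LightSignal:
        lux = _s_to_lux(self.variant, s, self.I_max, self.params)
        sig = LightSignal(edges, lux, I_max=self.I_max)
        if self.fixed_pre_light is not None:
            sig = self.fixed_pre_light.concat(sig)
        elif self.t_start < self.ctrl_start - 1e-9:
            sig = LightSignal.constant(0.0, self.t_start, self.ctrl_start).concat(sig)
        return sig

    def policy_of(self, switches: list[tuple[float, int]] | None) -> SleepPolicy:
        core: SleepPolicy
        if self.sleep_mode == "spontaneous" or switches is None:
            core = SpontaneousSleep()
        else:
            core = GuardedSchedule(switches)
        if self.forced_awake_until is not None:
            return PhasedPolicy([(self.forced_awake_until, ForcedAwake()), (math.inf, core)])
        return core

    def simulate(self, edges: np.ndarray, s: np.ndarray,
                 switches: list[tuple[float, int]] | None, t_f: float) -> HybridTrajectory:
        light = self.light_of(edges, s)
        pol = self.policy_of(switches)
        prc_fn = None if self.prc is None else self.prc.fast()
        return integrate_hybrid(self.state0, light, pol, (self.t_start, t_f),
                                self.params, dt=self.dt, prc=prc_fn)

    def residual_at_end(self, traj: HybridTrajectory) -> float:
        return terminal_residual(traj.Y[-1], float(traj.times[-1]),
                                 self.delta_init, self.cycle, self.spec)


def _realized_switches(traj: HybridTrajectory, after: float) -> list[tuple[float, int]]:
    return [(t, new) for (t, _old, new, _tag) in traj.switch_events if t >= after - 1e-9]


def _sim_project(prob: _Problem, edges: np.ndarray, s: np.ndarray,
                 switches: list[tuple[float, int]] | None, t_f: float,
                 max_wake: float = 18.0):
    """Simulate a candidate and project its schedule onto the constraints.

    The guarded schedule already clamps switch times into the sleepiness
    windows; on top of that, any realized wake interval longer than
    ``max_wake`` is shortened by scheduling the preceding wake earlier (the
    guard defers it to the B = B2_max crossing at worst, which raises H at
    wake and brings the next admissible sleep onset forward).
    """
    traj = prob.simulate(edges, s, switches, t_f)
    if switches is None:
        return traj, None
    for _ in range(3):
        sw = _realized_switches(traj, prob.ctrl_start)
        viol = None
        wake_t = None
        for (t, b) in sw:
            if b == 0:
                wake_t = t
            elif wake_t is not None and t - wake_t > max_wake + 1e-6:
                viol = (wake_t, t - wake_t - max_wake)
                break
        if viol is None:
            return traj, sw
        w, excess = viol
        moved = [(t - (excess + 0.25) if (b == 0 and abs(t - w) < 1e-6) else t, b)
                 for t, b in sw]
        traj = prob.simulate(edges, s, sorted(moved), t_f)
    return traj, _realized_switches(traj, prob.ctrl_start)


def _descent(
    prob: _Problem,
    t_f: float,
    s0: np.ndarray,
    switches0: list[tuple[float, int]] | None,
    *,
    max_iter: int = 40,
    stop_when_feasible: bool = True,
    step0: float = 0.5,
    switch_step_scale: float = 1.0,
    grad_tol: float = 1e-7,
) -> tuple[np.ndarray, list[tuple[float, int]] | None, float, int, list[float]]:
    """Projected gradient descent on the terminal residual at fixed horizon."""
    edges = prob.bin_edges(t_f)
    nb = len(edges) - 1
    s = np.clip(np.resize(np.asarray(s0, dtype=float), nb), 0.0, 1.0)
    switches = None if switches0 is None else [(min(t, t_f - 1e-6), b)
                                               for t, b in switches0 if t < t_f]
    traj, switches = _sim_project(prob, edges, s, switches, t_f)
    phi = prob.residual_at_end(traj)
    hist = [phi]
    step = step0
    it = 0
    for it in range(1, max_iter + 1):
        if stop_when_feasible and phi <= 0.0:
            break
        sched_times = [] if switches is None else [t for t, _b in switches]
        grad = adjoint_gradient(
            traj, edges, prob.delta_init, prob.cycle, prob.spec, prob.params,
            scheduled_times=sched_times, prc=prob.prc, I_max=prob.I_max,
        )
        g_s = grad.d_s
        g_norm2 = float(g_s @ g_s)
        g_sw = {}
        if switches is not None:
            g_sw = grad.d_switch
            g_norm2 += switch_step_scale * sum(v * v for v in g_sw.values())
        if g_norm2 < grad_tol**2:
            break
        # Armijo backtracking on the projected step
        improved = False
        for _ in range(12):
            s_new = np.clip(s - step * g_s, 0.0, 1.0)
            sw_new = None
            if switches is not None:
                sw_new = []
                for (tsw, bsw) in switches:
                    gi = g_sw.get(float(tsw), 0.0)
                    t_new = tsw - step * switch_step_scale * gi
                    t_new = min(max(t_new, prob.ctrl_start), t_f - 1e-6)
                    sw_new.append((t_new, bsw))
                sw_new.sort()
            traj_new, sw_new = _sim_project(prob, edges, s_new, sw_new, t_f)
            phi_new = prob.residual_at_end(traj_new)
            if phi_new < phi - 1e-12:
                s, switches, traj, phi = s_new, sw_new, traj_new, phi_new
                improved = True
                step = min(step * 1.8, 64.0)
                break
            step *= 0.35
            if step < 1e-7:
                break
        hist.append(phi)
        if not improved:
            break
    return s, switches, phi, it, hist


def _min_time(
    prob: _Problem,
    *,
    inits: list[tuple[float, np.ndarray, list[tuple[float, int]] | None]],
    resolution: float = 0.02,
    max_inner: int = 40,
    t_count_from: float = 0.0,
) -> OptimResult:
    """Shrink the horizon around fixed-horizon feasibility, trying warm
    starts in order of increasing horizon until one is confirmed feasible."""
    total_iter = 0
    best = None
    for t_feasible, s_init, switches_init in sorted(inits, key=lambda z: z[0]):
        s, sw, phi, its, hist = _descent(prob, t_feasible, s_init, switches_init,
                                         max_iter=max_inner)
        total_iter += its
        if phi <= 0.0:
            best = (t_feasible, s.copy(), None if sw is None else list(sw), phi, hist)
            break
    if best is None:
        return OptimResult(
            light=prob.light_of(prob.bin_edges(t_feasible), s),
            schedule=sw if sw is not None else "spontaneous",
            t_f=t_feasible - t_count_from, residual=phi, iterations=total_iter,
            objective_history=hist, converged=False,
            diagnostics={"note": "no initial horizon was feasible"},
        )
    t_feasible = best[0]
    # Horizon-shrinking continuation: reduce the horizon by a modest fraction
    # per probe so each inner descent starts from a nearby feasible schedule,
    # then bisect between the last feasible and first infeasible horizon.
    t_lo = t_count_from  # largest known-infeasible horizon
    t_hi = t_feasible
    shrink = 0.08
    while t_hi - t_lo > resolution:
        t_probe = max(t_hi - max(shrink * (t_hi - t_count_from), resolution),
                      0.5 * (t_lo + t_hi))
        s_mid = best[1]
        sw_mid = None if best[2] is None else [(t, b) for t, b in best[2] if t < t_probe]
        s2, sw2, phi2, its2, hist2 = _descent(prob, t_probe, s_mid, sw_mid,
                                              max_iter=max_inner)
        total_iter += its2
        if phi2 <= 0.0:
            t_hi = t_probe
            best = (t_probe, s2.copy(), None if sw2 is None else list(sw2), phi2, hist2)
        else:
            t_lo = t_probe
            shrink *= 0.5

    t_best, s_best, sw_best, phi_best, hist_best = best
    edges = prob.bin_edges(t_best)
    # polish: push the residual below zero with margin so the subsequent
    # bang-off thresholding keeps the horizon feasible
    s_pol, sw_pol, phi_pol, its_p, _ = _descent(
        prob, t_best, s_best, sw_best, max_iter=10, stop_when_feasible=False)
    total_iter += its_p
    if phi_pol <= phi_best:
        s_best, sw_best, phi_best = s_pol, sw_pol, phi_pol
    # bang-off thresholding at I_max/2, then re-verify feasibility; if the
    # midpoint cut breaks feasibility, scan a few other cut levels
    lux = _s_to_lux(prob.variant, s_best, prob.I_max, prob.params)
    bang_ok = False
    s_bang = s_best
    phi_bang = math.inf
    cuts = [prob.I_max / 2.0]
    interior = np.unique(lux[(lux > 0) & (lux < prob.I_max)])
    if len(interior):
        cuts += list(np.quantile(interior, [0.85, 0.65, 0.5, 0.35, 0.15, 0.02]))
    for cut in cuts:
        lux_c = np.where(lux >= cut, prob.I_max, 0.0)
        s_c = _lux_to_s(prob.variant, lux_c, prob.I_max, prob.params)
        traj_c, sw_c = _sim_project(prob, edges, s_c, sw_best, t_best)
        phi_c = prob.residual_at_end(traj_c)
        if phi_c <= 0.0:
            s_bang, phi_bang, bang_ok = s_c, phi_c, True
            traj, sw_best = traj_c, (sw_c if sw_c is not None else sw_best)
            break
    if bang_ok:
        s_best, phi_best = s_bang, phi_bang
    else:
        traj, sw_proj = _sim_project(prob, edges, s_best, sw_best, t_best)
        phi_best = prob.residual_at_end(traj)
        if sw_proj is not None:
            sw_best = sw_proj

    return OptimResult(
        light=prob.light_of(edges, s_best),
        schedule=sw_best if sw_best is not None else "spontaneous",
        t_f=t_best - t_count_from,
        residual=phi_best,
        iterations=total_iter,
        objective_history=hist_best,
        converged=True,
        diagnostics={"bang_off": bool(bang_ok), "resolution_h": resolution},
        trajectory=traj,
    )


@dataclass
class _CandidateInit:
    """A feasible warm start: horizon, light schedule and realized switches."""

    t_f: float
    light: LightSignal
    switches: list[tuple[float, int]]
    label: str = ""


def _build_candidate(prob: _Problem, mode: str, A: float, B_sleep: float,
                     B_wake: float, t_cap: float) -> _CandidateInit | None:
    """Day-structured maximal phase-shift schedule with an open-loop landing.

    Each waking period is dark for its first ``A`` hours and maximally lit
    afterwards ("delay" mode; reversed for "advance"), with the sleep
    automaton running at thresholds ``(B_sleep, B_wake)``.  At every wake the
    schedule may hand over to reference light + spontaneous sleep; the
    candidate keeps the handover with the earliest terminal crossing.
    """
    import dataclasses

    params = prob.params
    pp = dataclasses.replace(params, H_m=B_sleep, L_m=B_wake)
    dtc = max(prob.dt, 0.02)
    I_hi = prob.I_max
    prc_fn = None if prob.prc is None else prob.prc.fast()

    t = 0.0
    y = prob.state0.y.copy()
    beta = int(prob.state0.beta)
    t_wake = 0.0
    edges = [0.0]
    levels: list[float] = []
    switches: list[tuple[float, int]] = []
    handover: list[tuple[float, np.ndarray]] = []
    if beta == 0:
        handover.append((0.0, y.copy()))

    def run(I, t0, t1, b):
        sig = LightSignal.constant(I, t0, t1 + 1.0, I_max=max(I_hi, 1.0))
        st = TwoProcessState(prob.variant, y, beta=b)
        return integrate_hybrid(st, sig, SpontaneousSleep(), (t0, t1), pp,
                                dt=dtc, prc=prc_fn, max_switches=1)

    def log_light(I, t1):
        if t1 > edges[-1] + 1e-9:
            edges.append(t1)
            levels.append(I)

    guard = 0
    while t < t_cap and guard < 200:
        guard += 1
        if beta == 1:
            tr = run(0.0, t, t_cap, 1)
            t_new = float(tr.times[-1])
            log_light(0.0, t_new)
            y = tr.Y[-1].copy()
            t = t_new
            if tr.switch_events:
                beta = 0
                t_wake = t
                switches.append((t, 0))
                handover.append((t, y.copy()))
        else:
            t_on = min(t_wake + A, t_cap)
            fell_asleep = False
            if t < t_on - 1e-9:
                I0 = 0.0 if mode == "delay" else I_hi
                tr = run(I0, t, t_on, 0)
                t_new = float(tr.times[-1])
                log_light(I0, t_new)
                y = tr.Y[-1].copy()
                t = t_new
                if tr.switch_events:
                    beta = 1
                    switches.append((t, 1))
                    fell_asleep = True
            if not fell_asleep and t < t_cap - 1e-9:
                I1 = I_hi if mode == "delay" else 0.0
                tr = run(I1, t, t_cap, 0)
                t_new = float(tr.times[-1])
                log_light(I1, t_new)
                y = tr.Y[-1].copy()
                t = t_new
                if tr.switch_events:
                    beta = 1
                    switches.append((t, 1))

    best: _CandidateInit | None = None
    for (tw, yw) in handover:
        if best is not None and tw >= best.t_f:
            break
        t_end = min(t_cap, tw + 300.0)
        if t_end <= tw + 1.0:
            continue
        light_land = reference_light_signal(tw, t_end, delta_init=prob.delta_init,
                                            I_on=min(1000.0, I_hi))
        st = TwoProcessState(prob.variant, yw, beta=0)
        tr = integrate_hybrid(st, light_land, SpontaneousSleep(), (tw, t_end),
                              params, dt=dtc, prc=prc_fn)
        tf = first_crossing(tr, prob.delta_init, prob.cycle, prob.spec, t_min=tw)
        if tf is None or (best is not None and tf >= best.t_f):
            continue
        k = int(np.searchsorted(edges, tw))
        e = np.array(edges[:k] + [tw])
        lv = np.array(levels[: len(e) - 1])
        shift_sig = LightSignal(e, lv, I_max=max(I_hi, 1.0)) if len(lv) else None
        land_edges = light_land.edges
        land_mask = land_edges <= tf + 1e-9
        e2 = np.append(land_edges[land_mask], tf) if land_edges[land_mask][-1] < tf else land_edges[land_mask]
        lv2 = light_land.levels[: len(e2) - 1]
        land_sig = LightSignal(e2, lv2, I_max=max(I_hi, 1.0))
        full = land_sig if shift_sig is None else shift_sig.concat(land_sig)
        sw_full = [s for s in switches if s[0] < tw] + [
            (tt, nb) for (tt, _ob, nb, _tag) in tr.switch_events if tt < tf
        ]
        best = _CandidateInit(t_f=float(tf), light=full, switches=sw_full,
                              label=f"{mode}-A{A:g}")
    return best


def _candidate_inits(prob: _Problem, t_cap: float) -> list[_CandidateInit]:
    """Aggressive-shift warm starts for long entrainment problems."""
    if prob.t_start < 0.0 or prob.variant == "C3":
        return []
    p = prob.params
    if prob.sleep_mode == "controllable":
        modes = [("delay", p.B1_max, p.L_m), ("advance", p.H_m, p.B2_max)]
    else:
        modes = [("delay", p.H_m, p.L_m), ("advance", p.H_m, p.L_m)]
    out = []
    for mode, shi, wlo in modes:
        for A in (0.0, 4.0, 7.0, 10.0):
            cand = _build_candidate(prob, mode, A, shi, wlo, t_cap)
            if cand is not None:
                out.append(cand)
    out.sort(key=lambda c: c.t_f)
    return out


def _initial_guess(prob: _Problem, horizon_cap: float = 1000.0):
    """Open-loop run: feasible horizon, reference-light decision, realized switches."""
    ol = open_loop_entrain(
        prob.state0, prob.delta_init, prob.cycle, prob.spec, prob.params,
        t_start=prob.t_start, t_min=0.0,
        pre_light=prob.fixed_pre_light,
        pre_policy=ForcedAwake() if prob.forced_awake_until is not None else None,
        horizon_cap=horizon_cap, dt=prob.dt, prc=prob.prc,
        I_on=min(1000.0, prob.I_max),
    )
    if ol.t_f is None:
        raise RuntimeError(
            f"open-loop entrainment did not finish within {horizon_cap} h; "
            "cannot initialize the minimum-time search"
        )
    t_OL = max(ol.t_f, prob.ctrl_start + prob.bins_h)
    edges = prob.bin_edges(t_OL)
    mids = 0.5 * (edges[:-1] + edges[1:])
    I_ref = np.array([min(1000.0, prob.I_max)
                      if (math.fmod(math.fmod(m + prob.delta_init, 24.0) + 24.0, 24.0) < 16.0
                          and m >= 0.0)
                      else 0.0 for m in mids])
    s0 = _lux_to_s(prob.variant, I_ref, prob.I_max, prob.params)
    switches = _realized_switches(ol.trajectory, prob.ctrl_start)
    switches = [(t, b) for t, b in switches if t <= t_OL]
    return t_OL, s0, switches, ol


def minimize_time_spontaneous(
    state0: TwoProcessState,
    delta_init: float,
    cycle: ReferenceCycle,
    I_max: float,
    spec: TerminalSpec,
    params: ModelParams | None = None,
    *,
    bins_h: float = 0.1,
    dt: float = 0.005,
    resolution: float = 0.02,
    max_inner: int = 40,
    prc: PRCTable | None = None,
    t_start: float = 0.0,
    fixed_pre_light: LightSignal | None = None,
    forced_awake_until: float | None = None,
    shift_light_free: bool = False,
    horizon_cap: float = 1000.0,
) -> OptimResult:
    """Minimum-time entrainment with spontaneous sleep; light is the decision.

    When a forced-awake pre-phase is present (``t_start < 0``), the reported
    ``t_f`` is measured from t = 0 (the shift itself is excluded); with
    ``shift_light_free=True`` the light during the shift window becomes part
    of the decision as well.
    """
    params = params or ModelParams()
    prob = _Problem(
        variant=state0.variant, params=params, cycle=cycle, spec=spec,
        delta_init=delta_init, state0=state0, I_max=I_max,
        t_start=t_start,
        ctrl_start=t_start if shift_light_free else 0.0,
        fixed_pre_light=None if shift_light_free else fixed_pre_light,
        forced_awake_until=(0.0 if t_start < 0 else None) if forced_awake_until is None
                           else forced_awake_until,
        sleep_mode="spontaneous", bins_h=bins_h, dt=dt, prc=prc,
    )
    if terminal_residual(state0, t_start, delta_init, cycle, spec) <= 0.0 and t_start >= 0.0:
        empty = LightSignal.constant(0.0, t_start, t_start + 1e-3, I_max=I_max)
        return OptimResult(light=empty, schedule="spontaneous", t_f=0.0,
                           residual=terminal_residual(state0, t_start, delta_init, cycle, spec),
                           iterations=0, diagnostics={"already_entrained": True})
    t_OL, s0, _sw, _ol = _initial_guess(prob, horizon_cap)
    if shift_light_free and prob.ctrl_start < 0.0 and fixed_pre_light is not None:
        k_pre = int(np.sum(0.5 * (prob.bin_edges(t_OL)[:-1] + prob.bin_edges(t_OL)[1:]) < 0.0))
        pre_mids = 0.5 * (prob.bin_edges(t_OL)[:-1] + prob.bin_edges(t_OL)[1:])[:k_pre]
        s0[:k_pre] = _lux_to_s(prob.variant,
                               np.array([fixed_pre_light(m) for m in pre_mids]),
                               I_max, params)
    inits: list = [(t_OL, s0, None)]
    if t_OL > 48.0:
        for cand in _candidate_inits(prob, t_cap=t_OL)[:1]:
            if cand.t_f < t_OL - 1.0:
                e_c = prob.bin_edges(cand.t_f)
                mids_c = 0.5 * (e_c[:-1] + e_c[1:])
                s_c = _lux_to_s(prob.variant, np.array([cand.light(m) for m in mids_c]),
                                I_max, params)
                inits.append((cand.t_f, s_c, None))
    return _min_time(prob, inits=inits, resolution=resolution, max_inner=max_inner,
                     t_count_from=0.0)


def minimize_time_controllable(
    state0: TwoProcessState,
    delta_init: float,
    cycle: ReferenceCycle,
    I_max: float,
    spec: TerminalSpec,
    params: ModelParams | None = None,
    *,
    bins_h: float = 0.1,
    dt: float = 0.005,
    resolution: float = 0.02,
    max_inner: int = 40,
    prc: PRCTable | None = None,
    t_start: float = 0.0,
    fixed_pre_light: LightSignal | None = None,
    shift_light_free: bool = False,
    spontaneous_warm_start: OptimResult | None = None,
    horizon_cap: float = 1000.0,
) -> OptimResult:
    """Joint minimum-time optimization of light and sleep/wake switch times.

    Switch times are projected onto the feasible sleepiness windows by the
    guarded schedule (deferred until B enters the allowed band, forced at its
    edges), so every candidate satisfies the bound constraints by
    construction.  Episode counts are inherited from the spontaneous solution
    used as warm start.
    """
    params = params or ModelParams()
    if spontaneous_warm_start is None:
        spontaneous_warm_start = minimize_time_spontaneous(
            state0, delta_init, cycle, I_max, spec, params,
            bins_h=bins_h, dt=dt, resolution=resolution, max_inner=max_inner,
            prc=prc, t_start=t_start, fixed_pre_light=fixed_pre_light,
            shift_light_free=shift_light_free, horizon_cap=horizon_cap,
        )
    warm = spontaneous_warm_start
    if warm.t_f <= 0.0:
        return warm
    prob = _Problem(
        variant=state0.variant, params=params, cycle=cycle, spec=spec,
        delta_init=delta_init, state0=state0, I_max=I_max,
        t_start=t_start,
        ctrl_start=t_start if shift_light_free else 0.0,
        fixed_pre_light=None if shift_light_free else fixed_pre_light,
        forced_awake_until=0.0 if t_start < 0 else None,
        sleep_mode="controllable", bins_h=bins_h, dt=dt, prc=prc,
    )
    t_feas = warm.t_f
    edges = prob.bin_edges(t_feas)
    mids = 0.5 * (edges[:-1] + edges[1:])
    s0 = _lux_to_s(prob.variant, np.array([warm.light(m) for m in mids]), I_max, params)
    if warm.trajectory is not None:
        switches0 = _realized_switches(warm.trajectory, prob.ctrl_start)
    else:
        switches0 = []
    inits: list = [(t_feas, s0, switches0)]
    if t_feas > 48.0:
        for cand in _candidate_inits(prob, t_cap=t_feas)[:1]:
            if cand.t_f < t_feas - 1.0:
                e_c = prob.bin_edges(cand.t_f)
                mids_c = 0.5 * (e_c[:-1] + e_c[1:])
                s_c = _lux_to_s(prob.variant, np.array([cand.light(m) for m in mids_c]),
                                I_max, params)
                inits.append((cand.t_f, s_c, cand.switches))
    res = _min_time(prob, inits=inits, resolution=resolution, max_inner=max_inner,
                    t_count_from=0.0)
    if res.t_f > warm.t_f:  # never report worse than the feasible warm start
        warm.diagnostics["controllable_fallback"] = True
        return warm
    res.diagnostics["spontaneous_t_f"] = warm.t_f
    return res


# ---------------------------------------------------------------------------
# Process-C-only optimization, tuned sleep rule, reduced-model transfer
# ---------------------------------------------------------------------------

def tuned_sleep_rule(I_star: float, B: float, beta_prev: int,
                     params: ModelParams | None = None) -> int:
    """Sleep schedule slaved to a light-only optimum: wake whenever the
    optimal light is on or B is at the wake floor, sleep when it is dark and
    B is high, otherwise hold."""
    params = params or ModelParams()
    if I_star > 0.0 or B <= params.L_m:
        return 0
    if I_star == 0.0 and B >= params.H_m:
        return 1
    return beta_prev


def optimize_process_C_only(
    state0_C: TwoProcessState,
    delta_init: float,
    I_max: float,
    params: ModelParams | None = None,
    *,
    cycle_C: ReferenceCycle | None = None,
    tol: float = 0.01,
    bins_h: float = 0.1,
    dt: float = 0.005,
    resolution: float = 0.02,
    max_inner: int = 40,
    horizon_cap: float = 1000.0,
) -> OptimResult:
    """Minimum-time light-only entrainment of the circadian model (no sleep).

    The reference is the limit cycle of the circadian-only model under the
    effective 14.5 h : 9.5 h light-dark cycle that the reference subject
    actually receives (light 7:30 am - 10 pm; the 6 - 7:30 am light falls in
    the reference sleep period and is gated away).
    """
    from .reference import compute_entrained_cycle

    params = params or ModelParams()
    if cycle_C is None:
        cycle_C = compute_entrained_cycle("C3", params, photoperiod=(1.5, 16.0), dt=dt)
    spec = TerminalSpec(variant="C3", tol=tol)
    prob = _Problem(
        variant="C3", params=params, cycle=cycle_C, spec=spec,
        delta_init=delta_init, state0=state0_C, I_max=I_max,
        sleep_mode="spontaneous", bins_h=bins_h, dt=dt,
    )
    if terminal_residual(state0_C, 0.0, delta_init, cycle_C, spec) <= 0.0:
        empty = LightSignal.constant(0.0, 0.0, 1e-3, I_max=I_max)
        return OptimResult(light=empty, schedule="none", t_f=0.0, residual=-tol,
                           iterations=0, diagnostics={"already_entrained": True})
    # open-loop feasible horizon under the effective reference light
    light_ref = reference_light_signal(0.0, horizon_cap, delta_init=delta_init,
                                       I_on=min(1000.0, I_max), photoperiod=(1.5, 16.0))
    traj = integrate_hybrid(state0_C, light_ref, ForcedAwake(), (0.0, horizon_cap),
                            params, dt=dt)
    t_OL = first_crossing(traj, delta_init, cycle_C, spec)
    if t_OL is None:
        raise RuntimeError("circadian-only open-loop entrainment exceeded the horizon cap")
    edges = prob.bin_edges(max(t_OL, bins_h))
    mids = 0.5 * (edges[:-1] + edges[1:])
    s0 = _lux_to_s("C3", np.array([light_ref(m) for m in mids]), I_max, params)
    return _min_time(prob, inits=[(max(t_OL, bins_h), s0, None)],
                     resolution=resolution, max_inner=max_inner)


def drive_to_lux(u: np.ndarray | float, params: ModelParams | None = None) -> np.ndarray | float:
    """Invert the steady-state drive map u -> I (lux)."""
    params = params or ModelParams()
    scalar = np.isscalar(u)
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    Gg = params.G * params.gamma
    a = params.gamma * u_arr / np.maximum(Gg - u_arr, 1e-300)
    I = params.I0 * (a / params.alpha0) ** (1.0 / params.p)
    I = np.where(u_arr <= 0.0, 0.0, I)
    return float(I[0]) if scalar else I


def transfer_reduced_solution(
    reduced_result: OptimResult,
    variant_from: str,
    I_max: float,
    params: ModelParams | None = None,
    *,
    delta_init: float = 0.0,
) -> tuple[LightSignal, TransferSleepRule]:
    """Adapt a reduced-model (S+C1/S+C2) optimum for use on the full model.

    The reduced drive maps linearly onto lux, ``I = I_max u / u_max`` (bang-
    off stays bang-off), and the reduced sleep schedule is followed under
    sleepiness guards.  Past the reduced solution's end the returned light is
    the reference pattern and the schedule reverts to spontaneous (the
    supplement strategy); the light covers 1000 h of supplement.
    """
    params = params or ModelParams()
    if variant_from not in ("S+C1", "S+C2"):
        raise ValueError("variant_from must be one of S+C1, S+C2")
    u_max = steady_state_drive(I_max, params)[1]
    red = reduced_result.light
    u_levels = np.array([steady_state_drive(l, params)[1] for l in red.levels])
    I_levels = np.clip(I_max * u_levels / u_max, 0.0, I_max)
    t_end = float(red.edges[-1])
    light = LightSignal(red.edges, I_levels, I_max=I_max)
    supplement = reference_light_signal(t_end, t_end + 1000.0, delta_init=delta_init)
    light = light.concat(supplement)
    switches = [] if isinstance(reduced_result.schedule, str) else list(reduced_result.schedule)
    policy = TransferSleepRule(switches, t_end=t_end)
    return light, policy


def apply_transferred(
    state0: TwoProcessState,
    light: LightSignal,
    policy: TransferSleepRule,
    delta_init: float,
    cycle: ReferenceCycle,
    spec: TerminalSpec,
    params: ModelParams | None = None,
    *,
    dt: float = 0.005,
    horizon_cap: float = 1000.0,
) -> OpenLoopResult:
    """Run a transferred reduced-model solution on the full model and return
    its first terminal crossing."""
    params = params or ModelParams()
    t_end = min(float(light.edges[-1]), horizon_cap)
    traj = integrate_hybrid(state0, light, policy, (0.0, t_end), params, dt=dt)
    return OpenLoopResult(t_f=first_crossing(traj, delta_init, cycle, spec), trajectory=traj)
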