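"""Two-process model variants and a hybrid sleep/wake integrator.

The continuous dynamics combine three processes:

* **Process L** -- retinal light transduction.  A fraction ``n`` of retinal
  cells is in the "used" state; light activates ready cells at rate
  ``alpha(I) = alpha0 (I/I0)^p`` and produces the circadian drive
  ``u = G alpha (1 - n)``.  Light is gated off during sleep.
* **Process P** -- the core-body-temperature van der Pol-type oscillator with
  states ``(x, x_c)``, driven by ``u``.
* **Process S** -- the sleep homeostat ``H`` rising toward 1 while awake
  (time constant ``tau_r``) and decaying toward 0 while asleep (``tau_d``).

Sleepiness ``B = H - A_c x`` (or ``H - A_c cos(theta)`` for the phase-reduced
variant) drives the discrete sleep state ``beta`` through a hysteresis
automaton: spontaneous sleep onset when ``B`` rises to ``H_m`` and spontaneous
wake when ``B`` falls to ``L_m``.

Model variants
--------------
``S+C3``
    y = [n, x, x_c, H]; full third-order JFK circadian model + homeostat.
``S+C2``
    y = [x, x_c, H]; Process L replaced by its steady state, so the drive is
    a direct (gated) function of light.
``S+C1``
    y = [theta, H]; phase-reduced circadian model
    ``dtheta/dt = omega0 + f(theta) u`` with a tabulated phase response
    curve ``f``.
``C3``
    y = [n, x, x_c]; circadian-only model without Process S or sleep
    (used for light-only entrainment baselines).

Integration is fixed-step classical RK4 (default ``dt = 0.005`` h) with
bisection-based event localization for sleepiness-threshold crossings and
exact stopping at light breakpoints and scheduled switch times.  ``beta`` is
right-continuous: at a switch time the new mode applies from that instant on.
When a switch coincides with a light breakpoint the switch is processed
first, so the sleep gating sees the updated ``beta``.
"""

from __future__ import annotations

import bisect as _bisect
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .params import ModelParams, VARIANTS

__all__ = [
    "LightSignal",
    "TwoProcessState",
    "HybridTrajectory",
    "SleepPolicy",
    "SpontaneousSleep",
    "ForcedAwake",
    "ScheduledSleep",
    "TunedSleepRule",
    "TransferSleepRule",
    "alpha_of_light",
    "circadian_drive",
    "process_L_deriv",
    "process_P_deriv",
    "steady_state_drive",
    "homeostat_deriv",
    "sleepiness",
    "sleepiness_of",
    "phase_deriv",
    "spontaneous_transition",
    "controllable_transition",
    "integrate_hybrid",
    "reference_light",
    "reference_light_signal",
    "variant_dim",
    "state_names",
]

_PI12 = math.pi / 12.0
_EVENT_TOL = 1e-6  # h, bisection width for threshold-crossing localization
_T_EPS = 1e-9

_DIMS = {"S+C3": 4, "S+C2": 3, "S+C1": 2, "C3": 3}
_NAMES = {
    "S+C3": ("n", "x", "x_c", "H"),
    "S+C2": ("x", "x_c", "H"),
    "S+C1": ("theta", "H"),
    "C3": ("n", "x", "x_c"),
}


def variant_dim(variant: str) -> int:
    try:
        return _DIMS[variant]
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}") from None


def state_names(variant: str) -> tuple[str, ...]:
    variant_dim(variant)
    return _NAMES[variant]


# ---------------------------------------------------------------------------
# Elementary model functions
# ---------------------------------------------------------------------------

def alpha_of_light(I: float, beta: int, params: ModelParams) -> float:
    """Process L activation rate ``alpha0 * (I(1-beta)/I0)^p`` in 1/h.

    Sleep gates light completely: ``alpha = 0`` whenever ``beta == 1``.
    """
    if I < 0:
        raise ValueError(f"light intensity must be non-negative, got {I}")
    if beta or I == 0.0:
        return 0.0
    return params.alpha0 * (I / params.I0) ** params.p


def circadian_drive(n: float, I: float, beta: int, params: ModelParams) -> float:
    """Circadian drive ``u = G alpha(I, beta) (1 - n)`` onto Process P."""
    if not 0.0 <= n <= 1.0:
        raise ValueError(f"used-cell fraction n must lie in [0, 1], got {n}")
    return params.G * alpha_of_light(I, beta, params) * (1.0 - n)


def process_L_deriv(n: float, I: float, beta: int, params: ModelParams) -> float:
    """dn/dt = 60 (alpha(I,beta)(1-n) - gamma n); fast compared to Process P."""
    if not 0.0 <= n <= 1.0:
        raise ValueError(f"used-cell fraction n must lie in [0, 1], got {n}")
    a = alpha_of_light(I, beta, params)
    return 60.0 * (a * (1.0 - n) - params.gamma * n)


def process_P_deriv(x: float, x_c: float, u: float, params: ModelParams) -> tuple[float, float]:
    """Right-hand side of the core-body-temperature oscillator (dx/dt, dx_c/dt)."""
    mod = (1.0 - 0.4 * x) * (1.0 - params.k_c * x_c)
    dx = _PI12 * (
        x_c
        + params.mu * (x / 3.0 + (4.0 / 3.0) * x**3 - (256.0 / 105.0) * x**7)
        + mod * u
    )
    dxc = _PI12 * ((params.q * x_c - params.k * x) * mod * u - params.freq_sq * x)
    return dx, dxc


def steady_state_drive(I: float, params: ModelParams) -> tuple[float, float]:
    """Closed-form Process L equilibrium under constant light while awake.

    Returns ``(n_ss, u_ss)`` with ``n_ss = alpha/(alpha+gamma)`` and
    ``u_ss = G gamma alpha/(alpha+gamma)``; ``(0, 0)`` in darkness.
    """
    a = alpha_of_light(I, 0, params)
    if a == 0.0:
        return 0.0, 0.0
    n_ss = a / (a + params.gamma)
    return n_ss, params.G * params.gamma * n_ss


def homeostat_deriv(H: float, beta: int, params: ModelParams) -> float:
    """Process S: dH/dt = -H/tau_d asleep, (1-H)/tau_r awake."""
    return -H / params.tau_d if beta else (1.0 - H) / params.tau_r


def sleepiness_of(variant: str, y: Sequence[float], params: ModelParams) -> float:
    """Sleepiness B from the raw continuous state of a variant."""
    if variant == "S+C3":
        return y[3] - params.A_c * y[1]
    if variant == "S+C2":
        return y[2] - params.A_c * y[0]
    if variant == "S+C1":
        return y[1] - params.A_c * math.cos(y[0])
    raise ValueError(f"variant {variant!r} has no sleepiness (no Process S)")


def phase_deriv(theta: float, u: float, prc: Callable[[float], float], params: ModelParams) -> float:
    """Phase model dtheta/dt = omega0 + f(theta) u with tabulated PRC f."""
    if prc is None:
        raise ValueError("phase model requires a phase response curve (prc)")
    if u == 0.0:
        return params.omega0
    return params.omega0 + prc(theta) * u


def spontaneous_transition(B: float, beta_prev: int, params: ModelParams) -> int:
    """Hysteresis sleep automaton: sleep at B >= H_m, wake at B <= L_m, else hold."""
    if beta_prev == 0 and B >= params.H_m:
        return 1
    if beta_prev == 1 and B <= params.L_m:
        return 0
    return beta_prev


# ---------------------------------------------------------------------------
# Light schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LightSignal:
    """Piecewise-constant light intensity in lux.

    ``levels[j]`` applies on ``[edges[j], edges[j+1])``; the intensity is zero
    outside ``[edges[0], edges[-1])``.  All levels must lie in ``[0, I_max]``.
    """

    edges: np.ndarray
    levels: np.ndarray
    I_max: float = 10000.0

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        levels = np.asarray(self.levels, dtype=float)
        if edges.ndim != 1 or levels.ndim != 1 or len(edges) != len(levels) + 1:
            raise ValueError("need len(edges) == len(levels) + 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("light breakpoints must be strictly increasing")
        if np.any(levels < 0) or np.any(levels > self.I_max):
            raise ValueError("light levels must lie in [0, I_max]")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "levels", levels)

    @classmethod
    def constant(cls, level: float, t0: float, t1: float, I_max: float | None = None) -> "LightSignal":
        return cls(np.array([t0, t1]), np.array([level]), I_max=max(level, 1.0) if I_max is None else I_max)

    def __call__(self, t: float) -> float:
        return self.level_and_next(t)[0]

    def level_and_next(self, t: float) -> tuple[float, float]:
        """Intensity at time ``t`` and the time of the next breakpoint after ``t``."""
        edges = self.edges
        j = _bisect.bisect_right(edges, t + _T_EPS) - 1
        if j < 0:
            return 0.0, edges[0]
        if j >= len(self.levels):
            return 0.0, math.inf
        return float(self.levels[j]), float(edges[j + 1])

    def concat(self, other: "LightSignal") -> "LightSignal":
        """Join with a later signal; ``other`` must start where this one ends."""
        if abs(other.edges[0] - self.edges[-1]) > 1e-9:
            raise ValueError("signals to concatenate must abut")
        return LightSignal(
            np.concatenate([self.edges, other.edges[1:]]),
            np.concatenate([self.levels, other.levels]),
            I_max=max(self.I_max, other.I_max),
        )


def reference_light_signal(
    t0: float,
    t1: float,
    delta_init: float = 0.0,
    I_on: float = 1000.0,
    photoperiod: tuple[float, float] = (0.0, 16.0),
) -> LightSignal:
    """The 24-h reference light-dark cycle ``I_ref(t + delta_init)`` on [t0, t1].

    The reference pattern is ``I_on`` lux for ``mod(t, 24)`` in the
    photoperiod window (default ``[0, 16)``, i.e. 6 am - 10 pm) and darkness
    otherwise; ``delta_init`` shifts its anchor.
    """
    lo, hi = photoperiod
    edges = [t0]
    levels = []
    # candidate breakpoints of mod(t + delta_init, 24) hitting {lo, hi}
    day0 = math.floor((t0 + delta_init) / 24.0) - 1
    day1 = math.ceil((t1 + delta_init) / 24.0) + 1
    bps = sorted(
        b
        for d in range(day0, day1 + 1)
        for b in (24.0 * d + lo - delta_init, 24.0 * d + hi - delta_init)
        if t0 < b < t1
    )
    for b in bps + [t1]:
        mid = 0.5 * (edges[-1] + b)
        on = lo <= math.fmod(math.fmod(mid + delta_init, 24.0) + 24.0, 24.0) < hi
        levels.append(I_on if on else 0.0)
        edges.append(b)
    return LightSignal(np.array(edges), np.array(levels), I_max=max(I_on, 1.0))


def reference_light(t: float, variant: str = "S+C3", delta_init: float = 0.0) -> float:
    """Reference input at time ``t``: lux for S+C3/C3, drive u for reduced variants."""
    on = math.fmod(math.fmod(t + delta_init, 24.0) + 24.0, 24.0) < 16.0
    if variant in ("S+C3", "C3"):
        return 1000.0 if on else 0.0
    return 0.1731 if on else 0.0


# ---------------------------------------------------------------------------
# States and trajectories
# ---------------------------------------------------------------------------

@dataclass
class TwoProcessState:
    """Continuous state ``y`` of a model variant plus the discrete sleep state."""

    variant: str
    y: np.ndarray
    beta: int = 0

    def __post_init__(self) -> None:
        dim = variant_dim(self.variant)
        y = np.asarray(self.y, dtype=float)
        if y.shape != (dim,):
            raise ValueError(f"variant {self.variant} expects state of shape ({dim},)")
        names = state_names(self.variant)
        if "n" in names:
            n = y[names.index("n")]
            if not 0.0 <= n <= 1.0:
                raise ValueError(f"n must lie in [0, 1], got {n}")
        if "H" in names:
            H = y[names.index("H")]
            if not 0.0 <= H <= 1.0:
                raise ValueError(f"H must lie in [0, 1], got {H}")
        if "theta" in names:
            i = names.index("theta")
            y[i] = math.fmod(math.fmod(y[i], 2 * math.pi) + 2 * math.pi, 2 * math.pi)
        if self.beta not in (0, 1):
            raise ValueError("beta must be 0 (awake) or 1 (asleep)")
        self.y = y

    @property
    def B(self) -> float:
        return sleepiness_of(self.variant, self.y, ModelParams())


def sleepiness(state: TwoProcessState, params: ModelParams) -> float:
    """Sleepiness B = H - A_c x (or H - A_c cos theta for the phase variant)."""
    return sleepiness_of(state.variant, state.y, params)


@dataclass
class HybridTrajectory:
    """Dense output of a hybrid simulation.

    ``times`` are the RK4 grid nodes (plus exact event nodes); ``Y[i]`` is the
    continuous state at ``times[i]``; ``beta``/``I`` are right-continuous, so
    interval ``[times[i], times[i+1])`` evolves in mode ``beta[i]`` under
    schedule intensity ``I[i]``.  ``switch_events`` records every sleep-state
    change as ``(time, old_beta, new_beta, trigger)`` with trigger in
    ``{"spontaneous", "scheduled", "forced"}``.
    """

    variant: str
    times: np.ndarray
    Y: np.ndarray
    beta: np.ndarray
    I: np.ndarray
    switch_events: list[tuple[float, int, int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.times)

    def B(self, params: ModelParams) -> np.ndarray:
        if self.variant == "S+C3":
            return self.Y[:, 3] - params.A_c * self.Y[:, 1]
        if self.variant == "S+C2":
            return self.Y[:, 2] - params.A_c * self.Y[:, 0]
        if self.variant == "S+C1":
            return self.Y[:, 1] - params.A_c * np.cos(self.Y[:, 0])
        raise ValueError(f"variant {self.variant} has no sleepiness")

    def u(self, params: ModelParams) -> np.ndarray:
        """Circadian drive series (gated by the sleep state)."""
        gate = (self.beta == 0) & (self.I > 0)
        if self.variant in ("S+C3", "C3"):
            a = np.where(gate, params.alpha0 * (np.maximum(self.I, 1e-300) / params.I0) ** params.p, 0.0)
            return params.G * a * (1.0 - self.Y[:, 0])
        a = np.where(gate, params.alpha0 * (np.maximum(self.I, 1e-300) / params.I0) ** params.p, 0.0)
        return np.where(gate, params.G * params.gamma * a / (a + params.gamma), 0.0)

    def state_at(self, t: float) -> np.ndarray:
        """Linear interpolation of the continuous state at time ``t``."""
        cols = [np.interp(t, self.times, self.Y[:, j]) for j in range(self.Y.shape[1])]
        return np.array(cols)

    def beta_at(self, t: float) -> int:
        j = int(np.searchsorted(self.times, t + _T_EPS) - 1)
        return int(self.beta[max(0, min(j, len(self.beta) - 1))])

    def sleep_intervals(self) -> list[tuple[float, float]]:
        """Closed sleep episodes [(onset, wake), ...] within the simulated span."""
        out = []
        start = self.times[0] if self.beta[0] == 1 else None
        for (t, old, new, _tag) in self.switch_events:
            if old == 0 and new == 1:
                start = t
            elif old == 1 and new == 0 and start is not None:
                out.append((start, t))
                start = None
        if start is not None:
            out.append((start, float(self.times[-1])))
        return out


# ---------------------------------------------------------------------------
# Sleep policies
# ---------------------------------------------------------------------------

class SleepPolicy:
    """Base class: supplies threshold watches, scheduled switches and
    immediate (segment-start) transitions for the hybrid integrator."""

    def reset(self, t0: float, beta0: int) -> None:  # pragma: no cover - trivial
        pass

    def watches(self, t: float, beta: int, I: float, params: ModelParams) -> list[tuple[float, int, int, str]]:
        """Return [(level, direction, new_beta, trigger_tag), ...] on B."""
        return []

    def next_scheduled(self, t: float, beta: int) -> tuple[float, int]:
        """(time, new_beta) of the next scheduled switch after t, or (inf, -1)."""
        return math.inf, -1

    def immediate(self, t: float, beta: int, B: float, I: float, params: ModelParams):
        """Transition to apply right now, as (new_beta, tag), or None."""
        for level, direction, new_beta, tag in self.watches(t, beta, I, params):
            if direction > 0 and B >= level - 1e-12:
                return new_beta, tag
            if direction < 0 and B <= level + 1e-12:
                return new_beta, tag
        return None


class SpontaneousSleep(SleepPolicy):
    """Spontaneous schedule: sleep when B rises to H_m, wake when it falls to L_m."""

    def watches(self, t, beta, I, params):
        if beta == 0:
            return [(params.H_m, +1, 1, "spontaneous")]
        return [(params.L_m, -1, 0, "spontaneous")]


class ForcedAwake(SleepPolicy):
    """beta pinned to 0 regardless of sleepiness (night-shift work)."""

    def watches(self, t, beta, I, params):
        return []

    def immediate(self, t, beta, B, I, params):
        if beta == 1:
            return 0, "forced"
        return None


class ScheduledSleep(SleepPolicy):
    """Controllable schedule: switches at given times, with safety overrides.

    ``switches`` is a sorted list of ``(time, new_beta)``.  While awake the
    subject is forced asleep if B reaches ``B1_max``; while asleep, forced
    awake if B falls to ``L_m`` -- these keep the sleepiness bound constraints
    enforceable.  A scheduled switch into the current mode is a no-op.
    """

    def __init__(self, switches: Sequence[tuple[float, int]], safety: bool = True):
        self.switches = sorted((float(t), int(b)) for t, b in switches)
        self.safety = safety

    def watches(self, t, beta, I, params):
        if not self.safety:
            return []
        if beta == 0:
            return [(params.B1_max, +1, 1, "forced")]
        return [(params.L_m, -1, 0, "forced")]

    def next_scheduled(self, t, beta):
        for ts, b in self.switches:
            if ts > t + _T_EPS:
                return ts, b
        return math.inf, -1


class TunedSleepRule(SleepPolicy):
    """Sleep schedule slaved to a light-only optimal input ``I*``:

    awake whenever ``I*(t) > 0`` or ``B <= L_m``; asleep whenever
    ``I*(t) = 0`` and ``B >= H_m``; otherwise hold the previous state.
    """

    def __init__(self, light: LightSignal):
        self.light = light

    def watches(self, t, beta, I, params):
        if beta == 0 and I == 0.0:
            return [(params.H_m, +1, 1, "spontaneous")]
        if beta == 1:
            return [(params.L_m, -1, 0, "spontaneous")]
        return []

    def next_scheduled(self, t, beta):
        # light breakpoints already segment the integration; nothing extra
        return math.inf, -1

    def immediate(self, t, beta, B, I, params):
        if beta == 1 and I > 0.0:
            return 0, "scheduled"
        return super().immediate(t, beta, B, I, params)


class TransferSleepRule(SleepPolicy):
    """Follow a reduced-model sleep schedule, gated by sleepiness guards.

    Wake transitions of the reduced schedule are honored only once
    ``B <= B2_max``; sleep transitions only once ``B >= H_m``.  Independently,
    the subject is forced awake at ``B <= L_m`` and forced asleep at
    ``B >= B1_max``.  After the reduced schedule ends the automaton reverts to
    the spontaneous rule (supplement phase).
    """

    def __init__(self, switches: Sequence[tuple[float, int]], t_end: float):
        self.switches = sorted((float(t), int(b)) for t, b in switches)
        self.t_end = float(t_end)

    def _desired(self, t: float, beta: int) -> int:
        d = None
        for ts, b in self.switches:
            if ts <= t + _T_EPS:
                d = b
        return beta if d is None else d

    def watches(self, t, beta, I, params):
        if t >= self.t_end - _T_EPS:
            if beta == 0:
                return [(params.H_m, +1, 1, "spontaneous")]
            return [(params.L_m, -1, 0, "spontaneous")]
        desired = self._desired(t, beta)
        out = []
        if beta == 0:
            if desired == 1:
                out.append((params.H_m, +1, 1, "scheduled"))
            out.append((params.B1_max, +1, 1, "forced"))
        else:
            if desired == 0:
                out.append((params.B2_max, -1, 0, "scheduled"))
            out.append((params.L_m, -1, 0, "forced"))
        return out

    def next_scheduled(self, t, beta):
        for ts, _b in self.switches:
            if ts > t + _T_EPS:
                return ts, -2  # marker: re-evaluate desired state, no forced flip
        if t < self.t_end - _T_EPS:
            return self.t_end, -2
        return math.inf, -1


def controllable_transition(
    t: float,
    schedule: Sequence[tuple[float, int]],
    B: float,
    beta_prev: int,
    params: ModelParams,
) -> tuple[int, str | None]:
    """Apply the controllable-sleep automaton at time ``t``.

    Returns ``(new_beta, violation)`` where ``violation`` is None when the
    switch respects the sleepiness bound constraints
    ``H_m <= B(T_sleep) <= B1_max`` and ``L_m <= B(T_wake) <= B2_max``,
    and otherwise a human-readable report (the switch is still rejected,
    keeping ``beta_prev``).  Safety overrides force wake at ``B <= L_m`` and
    sleep at ``B >= B1_max`` regardless of the schedule.
    """
    for ts, b in schedule:
        if abs(ts - t) <= _EVENT_TOL and b != beta_prev:
            if b == 1 and not (params.H_m <= B <= params.B1_max):
                return beta_prev, (
                    f"scheduled sleep at t={t:.3f} rejected: B={B:.4f} outside "
                    f"[{params.H_m}, {params.B1_max}]"
                )
            if b == 0 and not (params.L_m <= B <= params.B2_max):
                return beta_prev, (
                    f"scheduled wake at t={t:.3f} rejected: B={B:.4f} outside "
                    f"[{params.L_m}, {params.B2_max}]"
                )
            return b, None
    if beta_prev == 1 and B <= params.L_m:
        return 0, None
    if beta_prev == 0 and B >= params.B1_max:
        return 1, None
    return beta_prev, None


# ---------------------------------------------------------------------------
# RK4 hybrid integrator
# ---------------------------------------------------------------------------

def _make_rhs(variant: str, params: ModelParams, beta: int, I: float,
              prc: Callable[[float], float] | None):
    """Build a fast scalar RHS closure for one constant-(beta, I) segment."""
    g = params.gamma
    mu, q, k, kc = params.mu, params.q, params.k, params.k_c
    w2 = params.freq_sq
    G = params.G
    if variant in ("S+C3", "C3"):
        a = 0.0 if (beta or I <= 0.0) else params.alpha0 * (I / params.I0) ** params.p
        if variant == "C3":
            def rhs(y):
                n, x, xc = y
                u = G * a * (1.0 - n)
                mod = (1.0 - 0.4 * x) * (1.0 - kc * xc)
                return (
                    60.0 * (a * (1.0 - n) - g * n),
                    _PI12 * (xc + mu * (x / 3.0 + 1.3333333333333333 * x**3
                                        - 2.4380952380952383 * x**7) + mod * u),
                    _PI12 * ((q * xc - k * x) * mod * u - w2 * x),
                )
            return rhs
        hdot = (lambda H: -H / params.tau_d) if beta else (lambda H: (1.0 - H) / params.tau_r)

        def rhs(y):
            n, x, xc, H = y
            u = G * a * (1.0 - n)
            mod = (1.0 - 0.4 * x) * (1.0 - kc * xc)
            return (
                60.0 * (a * (1.0 - n) - g * n),
                _PI12 * (xc + mu * (x / 3.0 + 1.3333333333333333 * x**3
                                    - 2.4380952380952383 * x**7) + mod * u),
                _PI12 * ((q * xc - k * x) * mod * u - w2 * x),
                hdot(H),
            )
        return rhs

    # reduced variants: drive is the gated steady-state value for this light
    a = 0.0 if (beta or I <= 0.0) else params.alpha0 * (I / params.I0) ** params.p
    u = 0.0 if a == 0.0 else G * g * a / (a + g)
    hdot = (lambda H: -H / params.tau_d) if beta else (lambda H: (1.0 - H) / params.tau_r)
    if variant == "S+C2":
        def rhs(y):
            x, xc, H = y
            mod = (1.0 - 0.4 * x) * (1.0 - kc * xc)
            return (
                _PI12 * (xc + mu * (x / 3.0 + 1.3333333333333333 * x**3
                                    - 2.4380952380952383 * x**7) + mod * u),
                _PI12 * ((q * xc - k * x) * mod * u - w2 * x),
                hdot(H),
            )
        return rhs
    if variant == "S+C1":
        if prc is None:
            raise ValueError("S+C1 integration requires a PRC table (prc=...)")
        w0 = params.omega0
        if u == 0.0:
            def rhs(y):
                return (w0, hdot(y[1]))
        else:
            def rhs(y):
                return (w0 + prc(y[0]) * u, hdot(y[1]))
        return rhs
    raise ValueError(f"unknown variant {variant!r}")


def _rk4_step(rhs, y, h):
    k1 = rhs(y)
    y2 = tuple(yi + 0.5 * h * ki for yi, ki in zip(y, k1))
    k2 = rhs(y2)
    y3 = tuple(yi + 0.5 * h * ki for yi, ki in zip(y, k2))
    k3 = rhs(y3)
    y4 = tuple(yi + h * ki for yi, ki in zip(y, k3))
    k4 = rhs(y4)
    hh = h / 6.0
    return tuple(
        yi + hh * (a + 2.0 * (b + c) + d) for yi, a, b, c, d in zip(y, k1, k2, k3, k4)
    )


def _B_func(variant: str, params: ModelParams):
    Ac = params.A_c
    if variant == "S+C3":
        return lambda y: y[3] - Ac * y[1]
    if variant == "S+C2":
        return lambda y: y[2] - Ac * y[0]
    if variant == "S+C1":
        return lambda y: y[1] - Ac * math.cos(y[0])
    return None


def integrate_hybrid(
    state0: TwoProcessState,
    light: LightSignal,
    policy: SleepPolicy,
    t_span: tuple[float, float],
    params: ModelParams | None = None,
    dt: float = 0.005,
    prc: Callable[[float], float] | None = None,
    max_switches: int | None = None,
) -> HybridTrajectory:
    """Simulate a model variant with hybrid sleep/wake switching.

    The continuous state is advanced piecewise with fixed-step RK4 between
    discrete events (sleepiness-threshold crossings, scheduled switches, and
    light breakpoints); threshold crossings are localized by bisection to
    1e-6 h.  Steps are aligned to the global ``dt`` grid so repeated runs are
    bitwise reproducible.

    Raises ``FloatingPointError`` if the state becomes non-finite.
    """
    params = params or ModelParams()
    if dt <= 0:
        raise ValueError("dt must be positive")
    t0, t_end = float(t_span[0]), float(t_span[1])
    if not (math.isfinite(t0) and math.isfinite(t_end) and t_end >= t0):
        raise ValueError("t_span must be finite with t_end >= t_start")
    variant = state0.variant
    no_sleep = variant == "C3"
    B_of = _B_func(variant, params)

    t = t0
    y = tuple(float(v) for v in state0.y)
    beta = 0 if no_sleep else int(state0.beta)
    policy.reset(t0, beta)

    times = [t]
    states = [y]
    betas = [beta]
    I_now, t_light_next = light.level_and_next(t)
    I_rec = [I_now]
    events: list[tuple[float, int, int, str]] = []

    def switch(new_beta: int, tag: str) -> None:
        nonlocal beta
        events.append((t, beta, new_beta, tag))
        beta = new_beta
        times.append(t)
        states.append(y)
        betas.append(beta)
        I_rec.append(I_now)

    guard = 0
    while t < t_end - _T_EPS and (max_switches is None or len(events) < max_switches):
        guard += 1
        if guard > 80_000_000:  # pragma: no cover - defensive
            raise RuntimeError("hybrid integration exceeded event budget")
        I_now, t_light_next = light.level_and_next(t)
        I_rec[-1] = I_now
        if not no_sleep:
            imm = policy.immediate(t, beta, B_of(y), I_now, params)
            if imm is not None and imm[0] != beta:
                switch(*imm)
                continue
        t_sched, sched_beta = (math.inf, -1) if no_sleep else policy.next_scheduled(t, beta)
        t_stop = min(t_end, t_light_next, t_sched)
        rhs = _make_rhs(variant, params, beta, I_now, prc)
        watch = [] if no_sleep else policy.watches(t, beta, I_now, params)

        hit = None
        while t < t_stop - _T_EPS:
            k_grid = math.floor(t / dt + 1e-9) + 1
            t_next = min(t_stop, k_grid * dt)
            if t_next <= t + _T_EPS:
                t_next = min(t_stop, (k_grid + 1) * dt)
            h = t_next - t
            try:
                y_new = _rk4_step(rhs, y, h)
            except OverflowError as exc:
                raise FloatingPointError(
                    f"state blew up near t={t_next:.4f} (variant {variant}, beta={beta})"
                ) from exc
            if not all(math.isfinite(v) for v in y_new):
                raise FloatingPointError(
                    f"non-finite state at t={t_next:.4f} (variant {variant}, beta={beta})"
                )
            if watch:
                B1 = B_of(y_new)
                for level, direction, new_beta, tag in watch:
                    if (direction > 0 and B1 >= level) or (direction < 0 and B1 <= level):
                        hit = (level, direction, new_beta, tag)
                        break
            if hit is not None:
                level, direction, new_beta, tag = hit
                lo, hi = 0.0, h
                while hi - lo > _EVENT_TOL:
                    mid = 0.5 * (lo + hi)
                    Bm = B_of(_rk4_step(rhs, y, mid))
                    crossed = Bm >= level if direction > 0 else Bm <= level
                    if crossed:
                        hi = mid
                    else:
                        lo = mid
                y = _rk4_step(rhs, y, hi)
                t = t + hi
                times.append(t)
                states.append(y)
                betas.append(beta)
                I_rec.append(I_now)
                break
            y = y_new
            t = t_next
            times.append(t)
            states.append(y)
            betas.append(beta)
            I_rec.append(I_now)
        if hit is not None:
            switch(hit[2], hit[3])
            continue
        t = max(t, min(t_stop, t_end))
        if t_sched <= min(t_end, t_light_next) + _T_EPS and t >= t_sched - _T_EPS:
            if sched_beta in (0, 1) and sched_beta != beta:
                switch(sched_beta, "scheduled")
            elif sched_beta == -2 or sched_beta == beta:
                # schedule marker or no-op switch: just re-enter the loop so the
                # policy can refresh its watches / desired state
                imm = None if no_sleep else policy.immediate(t, beta, B_of(y), I_now, params)
                if imm is not None and imm[0] != beta:
                    switch(*imm)

    return HybridTrajectory(
        variant=variant,
        times=np.array(times),
        Y=np.array(states),
        beta=np.array(betas, dtype=np.int8),
        I=np.array(I_rec),
        switch_events=events,
    )
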