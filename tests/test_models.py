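"""Unit and property tests for the model right-hand sides, sleep automata
and the hybrid integrator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circentrain import (
    ForcedAwake,
    LightSignal,
    ModelParams,
    ScheduledSleep,
    SpontaneousSleep,
    TwoProcessState,
    alpha_of_light,
    circadian_drive,
    controllable_transition,
    homeostat_deriv,
    integrate_hybrid,
    process_L_deriv,
    process_P_deriv,
    reference_light,
    reference_light_signal,
    sleepiness,
    spontaneous_transition,
    steady_state_drive,
)

P = ModelParams()


# ---------------------------------------------------------------------------
# Elementary operations (hand-evaluated expectations)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("I,beta,expected", [
    (1000.0, 0, 0.05 * math.sqrt(1000.0 / 9500.0)),  # 0.0162221...
    (0.0, 0, 0.0),
    (10000.0, 1, 0.0),  # sleep gates light entirely
])
def test_alpha_of_light(I, beta, expected):
    assert alpha_of_light(I, beta, P) == pytest.approx(expected, abs=1e-9)


def test_alpha_rejects_negative_light():
    with pytest.raises(ValueError):
        alpha_of_light(-1.0, 0, P)


@pytest.mark.parametrize("n,I,beta,expected", [
    (1.0, 5000.0, 0, 0.0),                        # no ready cells
    (0.5, 1000.0, 1, 0.0),                        # sleep gating
    (0.6839419, 1000.0, 0, 0.17309),              # steady-state n at 1000 lux
])
def test_circadian_drive(n, I, beta, expected):
    assert circadian_drive(n, I, beta, P) == pytest.approx(expected, abs=5e-5)


def test_circadian_drive_domain():
    with pytest.raises(ValueError):
        circadian_drive(1.2, 100.0, 0, P)


@pytest.mark.parametrize("n,I,expected", [
    (0.0, 0.0, 0.0),
    (0.5, 0.0, -60.0 * 0.0075 * 0.5),
])
def test_process_L_deriv(n, I, expected):
    assert process_L_deriv(n, I, 0, P) == pytest.approx(expected, abs=1e-12)


def test_process_L_equilibrium():
    n_ss, _ = steady_state_drive(1000.0, P)
    assert process_L_deriv(n_ss, 1000.0, 0, P) == pytest.approx(0.0, abs=1e-12)


def test_process_P_deriv_hand_values():
    dx, dxc = process_P_deriv(0.0, 0.0, 0.0, P)
    assert (dx, dxc) == (0.0, 0.0)
    dx, dxc = process_P_deriv(1.0, 0.0, 0.0, P)
    assert dx == pytest.approx(math.pi / 12 * 0.13 * (1 / 3 + 4 / 3 - 256 / 105))
    assert dxc == pytest.approx(-math.pi / 12 * (24.0 / (0.99729 * 24.2)) ** 2)


def test_steady_state_drive_printed_values():
    assert steady_state_drive(1000.0, P)[1] == pytest.approx(0.1731, abs=5e-5)
    assert steady_state_drive(10000.0, P)[1] == pytest.approx(0.2208, abs=5e-5)
    assert steady_state_drive(0.0, P) == (0.0, 0.0)


@pytest.mark.parametrize("H,beta,expected", [
    (1.0, 0, 0.0),
    (0.0, 1, 0.0),
    (0.5, 1, -0.5 / 4.2),
])
def test_homeostat_deriv(H, beta, expected):
    assert homeostat_deriv(H, beta, P) == pytest.approx(expected)


def test_sleepiness_variants():
    s3 = TwoProcessState("S+C3", np.array([0.5, 0.0, 0.0, 0.67]))
    assert sleepiness(s3, P) == pytest.approx(0.67)
    s3 = TwoProcessState("S+C3", np.array([0.5, 1.0, 0.0, 0.5]))
    assert sleepiness(s3, P) == pytest.approx(0.5 - 0.1333)
    s1 = TwoProcessState("S+C1", np.array([math.pi, 0.5]))
    assert sleepiness(s1, P) == pytest.approx(0.5 + 0.1333)


@pytest.mark.parametrize("B,prev,expected", [
    (0.67, 0, 1),   # tired enough to sleep
    (0.4, 0, 0),    # hysteresis hold awake
    (0.4, 1, 1),    # hysteresis hold asleep
    (0.17, 1, 0),   # spontaneous wake
])
def test_spontaneous_transition(B, prev, expected):
    assert spontaneous_transition(B, prev, P) == expected


def test_controllable_transition_bounds():
    sched = [(10.0, 1)]
    beta, viol = controllable_transition(10.0, sched, 0.72, 0, P)
    assert beta == 1 and viol is None
    beta, viol = controllable_transition(10.0, sched, 0.80, 0, P)
    assert beta == 0 and viol is not None and "rejected" in viol
    beta, viol = controllable_transition(5.0, [(5.0, 0)], 0.27, 1, P)
    assert beta == 0 and viol is None
    # safety overrides win regardless of the schedule
    assert controllable_transition(3.0, sched, 0.16, 1, P) == (0, None)
    assert controllable_transition(3.0, [], 0.78, 0, P) == (1, None)


# ---------------------------------------------------------------------------
# Parameter and signal validation
# ---------------------------------------------------------------------------

def test_params_invariants():
    with pytest.raises(ValueError):
        ModelParams(gamma=-1.0)
    with pytest.raises(ValueError):
        ModelParams(L_m=0.7, H_m=0.6)
    with pytest.raises(ValueError):
        ModelParams(B1_max=0.5)


def test_light_signal_validation():
    with pytest.raises(ValueError):
        LightSignal(np.array([0.0, 1.0]), np.array([-5.0]))
    with pytest.raises(ValueError):
        LightSignal(np.array([1.0, 0.0]), np.array([100.0]))
    with pytest.raises(ValueError):
        LightSignal(np.array([0.0, 1.0]), np.array([2000.0]), I_max=1000.0)
    sig = LightSignal(np.array([0.0, 2.0, 4.0]), np.array([100.0, 0.0]))
    assert sig(1.0) == 100.0 and sig(3.0) == 0.0 and sig(10.0) == 0.0


def test_reference_light_pattern():
    assert reference_light(8.0) == 1000.0
    assert reference_light(16.0) == 0.0
    assert reference_light(32.0) == 1000.0        # periodicity: 32 mod 24 = 8
    assert reference_light(40.0) == 0.0           # 40 mod 24 = 16, dark band
    assert reference_light(8.0, "S+C2") == 0.1731  # reduced variants get drive
    sig = reference_light_signal(0.0, 48.0)
    for t in (8.0, 15.9, 16.1, 23.9, 24.1, 32.0, 40.0):
        assert sig(t) == reference_light(t)


# ---------------------------------------------------------------------------
# Hybrid integration
# ---------------------------------------------------------------------------

def test_wake_homeostat_saturates():
    st = TwoProcessState("S+C3", np.array([0.0, 0.2, 0.1, 0.3]), beta=0)
    dark = LightSignal.constant(0.0, 0.0, 120.0)
    traj = integrate_hybrid(st, dark, ForcedAwake(), (0.0, 120.0), P, dt=0.02)
    H = traj.Y[:, 3]
    assert np.all(np.diff(H) >= -1e-12)
    assert H[-1] > 0.99


def test_sleep_decouples_light():
    """With beta = 1 the drive is exactly zero, so the circadian subsystem is
    identical under any light level."""
    y0 = np.array([0.5, 0.3, -0.8, 0.6])
    out = []
    for I in (0.0, 10000.0):
        st = TwoProcessState("S+C3", y0.copy(), beta=1)
        sig = LightSignal.constant(I, 0.0, 6.0)
        pol = ScheduledSleep([], safety=False)  # stay asleep
        traj = integrate_hybrid(st, sig, pol, (0.0, 6.0), P, dt=0.01)
        out.append(traj.Y[:, 1:3])
    assert np.array_equal(out[0], out[1])


def test_spontaneous_hysteresis_events():
    st = TwoProcessState("S+C3", np.array([0.5, 1.0, 0.0, 0.5]), beta=0)
    light = reference_light_signal(0.0, 72.0)
    traj = integrate_hybrid(st, light, SpontaneousSleep(), (0.0, 72.0), P, dt=0.01)
    events = traj.switch_events
    assert len(events) >= 3
    B = traj.B(P)
    for (t, old, new, tag) in events:
        assert tag == "spontaneous"
        i = np.searchsorted(traj.times, t)
        level = P.H_m if new == 1 else P.L_m
        assert B[i] == pytest.approx(level, abs=1e-4)
    # beta alternates and only changes at events
    flips = np.nonzero(np.diff(traj.beta))[0]
    assert len(flips) == len(events)


def test_event_time_against_fine_reference():
    """First sleep onset agrees with a 100x-finer fixed-step integration."""
    st = TwoProcessState("S+C3", np.array([0.5, 1.0, 0.0, 0.5]), beta=0)
    light = reference_light_signal(0.0, 24.0)
    coarse = integrate_hybrid(st, light, SpontaneousSleep(), (0.0, 24.0), P, dt=0.05)
    fine = integrate_hybrid(st, light, SpontaneousSleep(), (0.0, 24.0), P, dt=0.0005)
    t_coarse = coarse.switch_events[0][0]
    t_fine = fine.switch_events[0][0]
    assert abs(t_coarse - t_fine) < 1e-3


def test_dt_convergence():
    """Halving dt moves the 48-h terminal state far less than the step size
    itself (4th-order one-step method)."""
    st = TwoProcessState("S+C3", np.array([0.5, 1.0, 0.0, 0.5]), beta=0)
    light = reference_light_signal(0.0, 48.0)
    ends = {}
    for dt in (0.02, 0.01):
        traj = integrate_hybrid(st, light, SpontaneousSleep(), (0.0, 48.0), P, dt=dt)
        ends[dt] = traj.Y[-1]
    assert np.max(np.abs(ends[0.02] - ends[0.01])) < 1e-5


def test_forced_awake_pins_beta():
    st = TwoProcessState("S+C3", np.array([0.6, -0.5, -0.5, 0.9]), beta=0)
    sig = LightSignal.constant(0.0, 0.0, 24.0)
    traj = integrate_hybrid(st, sig, ForcedAwake(), (0.0, 24.0), P, dt=0.02)
    assert np.all(traj.beta == 0)


def test_nonfinite_state_raises():
    st = TwoProcessState("S+C3", np.array([0.5, 1e3, -1e3, 0.5]), beta=0)
    sig = LightSignal.constant(0.0, 0.0, 24.0)
    with pytest.raises(FloatingPointError):
        integrate_hybrid(st, sig, ForcedAwake(), (0.0, 24.0), P, dt=0.5)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(
    n0=st.floats(0.05, 0.95),
    H0=st.floats(0.2, 0.65),
    x0=st.floats(-1.0, 1.0),
    I=st.floats(0.0, 10000.0),
)
def test_state_bounds_invariant(n0, H0, x0, I):
    """n and H remain inside [0, 1] for any admissible start and light."""
    st0 = TwoProcessState("S+C3", np.array([n0, x0, 0.0, H0]), beta=0)
    sig = LightSignal.constant(I, 0.0, 30.0, I_max=10000.0)
    traj = integrate_hybrid(st0, sig, SpontaneousSleep(), (0.0, 30.0), P, dt=0.02)
    assert np.all(traj.Y[:, 0] >= -1e-9) and np.all(traj.Y[:, 0] <= 1.0 + 1e-9)
    assert np.all(traj.Y[:, 3] >= -1e-9) and np.all(traj.Y[:, 3] <= 1.0 + 1e-9)
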