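"""Tests for entrained reference cycles, circadian phase and PRC estimation.

The published entrained-state samples act as oracles for the limit-cycle
search: the x/H values at 10 am and 10 pm and the spontaneous sleep window
of the reference subject are asserted to the precision the model itself
reproduces them (5e-3 absolute on states, 15 min on clock times).
"""

import math

import numpy as np
import pytest

from circentrain import (
    ModelParams,
    PRCTable,
    ReferenceCycle,
    compute_entrained_cycle,
    estimate_prc,
    free_running_period,
    phase_of,
    reference_phase,
    reference_state,
)

TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# Circadian phase
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x,xc,expected", [
    (1.0, 0.0, 0.0),
    (-1.0, 0.0, math.pi),
    (0.0, -1.0, math.pi / 2),
    (0.0, 1.0, 3 * math.pi / 2),
])
def test_phase_of(x, xc, expected):
    assert phase_of(x, xc) == pytest.approx(expected)


def test_phase_of_origin_undefined():
    with pytest.raises(ValueError):
        phase_of(0.0, 0.0)


# ---------------------------------------------------------------------------
# Entrained S+C3 cycle
# ---------------------------------------------------------------------------

def test_cycle_periodicity_and_structure(cycle3):
    assert cycle3.residual < 1e-8
    assert len(cycle3.switch_times) == 2  # exactly one sleep episode
    # 24-h periodic although the free-running period is 24.2 h
    assert np.allclose(cycle3.state(0.0), cycle3.state(24.0), atol=1e-6)


def test_cycle_reproduces_published_samples(cycle3):
    n4, x4, xc4, H4 = cycle3.state(4.0)   # 10 am
    assert x4 == pytest.approx(0.0815, abs=5e-3)
    assert H4 == pytest.approx(0.1984, abs=5e-3)
    assert n4 == pytest.approx(0.6631, abs=5e-3)
    assert xc4 == pytest.approx(1.0459, abs=5e-3)
    _, x16, xc16, H16 = cycle3.state(16.0)  # 10 pm
    assert H16 == pytest.approx(0.5854, abs=5e-3)
    assert x16 == pytest.approx(-0.0479, abs=5e-3)
    assert xc16 == pytest.approx(-1.3003, abs=5e-3)


def test_reference_sleep_window(cycle3):
    onset, wake = cycle3.sleep_window()
    # about 11:10 pm to 7:30 am, i.e. 17.17 h and 1.5 h past 6 am (+- 15 min)
    assert onset == pytest.approx(17.17, abs=0.25)
    assert wake == pytest.approx(1.5, abs=0.25)


def test_reference_state_lookup(cycle3):
    s = reference_state(0.0, 4.0, cycle3)
    assert np.allclose(s.y, cycle3.state(4.0))
    s24 = reference_state(24.0, 1.0, cycle3)
    s0 = reference_state(0.0, 1.0, cycle3)
    assert np.allclose(s24.y, s0.y, atol=1e-9)
    assert reference_state(0.0, 16.0, cycle3).y[3] == pytest.approx(0.5854, abs=5e-3)
    assert reference_state(0.0, 20.0, cycle3).beta == 1  # 2 am: asleep


def test_reference_phase_consistency(cycle3):
    ts = np.arange(0.0, 24.0, 0.25)
    th = np.array([reference_phase(cycle3, t) for t in ts])
    x = cycle3.state(ts)[:, 1]
    # the orbit is close to (but not exactly) the unit circle; the x_c
    # amplitude reaches ~1.3, so x ~ cos(theta) only to a couple of tenths
    assert np.max(np.abs(np.cos(th) - x)) < 0.3
    # theta_ref advances ~2 pi per 24 h
    assert reference_phase(cycle3, 5.0) == pytest.approx(
        reference_phase(cycle3, 29.0), abs=1e-6)
    unwrapped = np.unwrap(th)
    assert unwrapped[-1] - unwrapped[0] == pytest.approx(TWO_PI * 23.75 / 24, rel=0.02)


def test_cycle_json_roundtrip(cycle3, tmp_path):
    path = tmp_path / "cycle.json"
    cycle3.to_json(path)
    back = ReferenceCycle.from_json(path)
    assert back.variant == cycle3.variant
    assert np.allclose(back.state(7.3), cycle3.state(7.3), atol=1e-9)
    assert back.sleep_window() == cycle3.sleep_window()


# ---------------------------------------------------------------------------
# Free-running oscillator and PRC
# ---------------------------------------------------------------------------

def test_free_running_period(params):
    T = free_running_period(params, n_cycles=5, dt=0.01)
    assert T == pytest.approx(24.2, abs=0.05)


def test_prc_zero_pulse_is_zero(params):
    table = estimate_prc(params, pulse_u=0.0, n_theta=16)
    assert np.all(table.f == 0.0)


def test_prc_shape_and_sign_regions(prc, cycle3):
    f = prc.f
    # both advance and delay regions exist, with at least two zero crossings
    assert f.max() > 0.05 and f.min() < -0.05
    sign_flips = np.sum(np.abs(np.diff(np.sign(f))) > 0)
    assert sign_flips >= 2
    # mapped to the reference clock: advance from ~7:30 am to ~5 pm, delay
    # from ~5 pm to ~11:10 pm (sampled 45 min inside each region)
    for t in np.arange(2.25, 10.3, 1.0):       # 8:15 am .. 4:15 pm
        assert prc(reference_phase(cycle3, t)) > 0.0
    for t in np.arange(11.75, 16.5, 1.0):      # 5:45 pm .. 10:30 pm
        assert prc(reference_phase(cycle3, t)) < 0.0


def test_prc_reproduces_pulse_shift(prc, params):
    """Integrating the phase model through a 30-min pulse reproduces the
    2nd-order model's asymptotic shift (which is what the table encodes)."""
    # forward-Euler fine integration of dtheta/dt = w0 + f(theta) u over the pulse
    for th0 in (0.8, 2.5, 4.4):
        th = th0
        dt = 1e-3
        for _ in range(int(prc.pulse_len_h / dt)):
            th += dt * (params.omega0 + prc(th) * prc.pulse_u)
        shift_phase_model = th - th0 - params.omega0 * prc.pulse_len_h
        # table prediction at the pulse mid-phase
        predicted = prc(th0 + 0.5 * params.omega0 * prc.pulse_len_h) * prc.pulse_u * prc.pulse_len_h
        assert shift_phase_model == pytest.approx(predicted, abs=0.05 * TWO_PI)


def test_phase_deriv_uses_prc(prc, params):
    from circentrain import phase_deriv

    # zero drive: free-running frequency regardless of phase
    assert phase_deriv(0.7, 0.0, prc, params) == pytest.approx(params.omega0)
    # at a PRC zero crossing the drive has no effect
    th_grid = np.linspace(0, TWO_PI, 2000)
    f = prc(th_grid)
    i = int(np.nonzero(np.diff(np.sign(f)))[0][0])
    th0 = th_grid[i] - f[i] * (th_grid[i + 1] - th_grid[i]) / (f[i + 1] - f[i])
    assert phase_deriv(th0, 0.1731, prc, params) == pytest.approx(params.omega0, abs=1e-4)
    # positive PRC advances the phase under drive
    th_adv = th_grid[int(np.argmax(f))]
    assert phase_deriv(th_adv, 0.1731, prc, params) > params.omega0
    with pytest.raises(ValueError):
        phase_deriv(0.5, 0.1, None, params)


def test_prc_json_roundtrip(prc, tmp_path):
    path = tmp_path / "prc.json"
    prc.to_json(path)
    back = PRCTable.from_json(path)
    assert np.allclose(back.f, prc.f)
    assert back(1.234) == pytest.approx(prc(1.234), abs=1e-12)


# ---------------------------------------------------------------------------
# Reduced-variant cycles
# ---------------------------------------------------------------------------

def test_reduced_cycles_close_to_full(params, cycle3, prc):
    """The entrained cycles of the reduced variants track the full model.

    They sit slightly later in phase (the reduced drives lack the Process L
    morning transient), so closeness is asserted as a bounded phase offset
    and bounded state discrepancy rather than pointwise identity.
    """
    c2 = compute_entrained_cycle("S+C2", params)
    ts = np.arange(0.0, 24.0, 0.05)
    x3 = cycle3.state(ts)[:, 1]
    x2 = c2.state(ts)[:, 0]

    def upcross(x):
        i = int(np.nonzero((x[:-1] < 0) & (x[1:] >= 0))[0][0])
        return ts[i] - x[i] * (ts[i + 1] - ts[i]) / (x[i + 1] - x[i])

    assert abs(upcross(x2) - upcross(x3)) < 1.5          # phase offset, h
    assert np.max(np.abs(x2 - x3)) < 0.35
    on3, wk3 = cycle3.sleep_window()
    on2, wk2 = c2.sleep_window()
    assert abs(on2 - on3) < 1.5 and abs(wk2 - wk3) < 1.5

    c1 = compute_entrained_cycle("S+C1", params, prc=prc)
    on1, wk1 = c1.sleep_window()
    assert abs(on1 - on3) < 2.0 and abs(wk1 - wk3) < 2.0
    # H stays comparable across variants
    H3 = cycle3.state(ts)[:, 3]
    H1 = c1.state(ts)[:, 1]
    assert np.max(np.abs(H1 - H3)) < 0.25
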