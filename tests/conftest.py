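"""Shared fixtures: default parameters, reference cycles, PRC, and one small
optimized jet-lag case reused across optimizer and feedback tests.

Heavy objects are session-scoped; the reference cycle and PRC are computed
once per test run.  Optimizer fixtures use coarsened numerics (dt = 0.02 h,
0.5-1 h light bins) so the suite stays within a desk-time budget; the
problem sizes are stated where results are asserted.
"""

from __future__ import annotations

import numpy as np
import pytest

from circentrain import (
    ModelParams,
    TerminalSpec,
    TwoProcessState,
    compute_entrained_cycle,
    estimate_prc,
    minimize_time_controllable,
    minimize_time_spontaneous,
)


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def cycle3(params):
    """Entrained S+C3 reference limit cycle at default numerics."""
    return compute_entrained_cycle("S+C3", params)


@pytest.fixture(scope="session")
def spec3() -> TerminalSpec:
    return TerminalSpec("S+C3", 0.01)


@pytest.fixture(scope="session")
def prc(params):
    """PRC of the 2nd-order oscillator (96 phases, dt = 0.01 h)."""
    return estimate_prc(params, n_theta=96, dt=0.01)


def jetlag_state(cycle, delta_shift: float, delta_init: float = 1.0) -> TwoProcessState:
    arg = delta_shift + delta_init
    return TwoProcessState("S+C3", cycle.state(arg), beta=cycle.beta_at(arg))


@pytest.fixture(scope="session")
def small_spont_result(params, cycle3, spec3):
    """Minimum-time spontaneous solution for a 4-h eastward shift at 10 klux."""
    st = jetlag_state(cycle3, 4.0)
    return minimize_time_spontaneous(st, 1.0, cycle3, 10000.0, spec3, params,
                                     bins_h=0.5, dt=0.02, resolution=1.0, max_inner=25)


@pytest.fixture(scope="session")
def small_ctrl_result(params, cycle3, spec3, small_spont_result):
    """Controllable-sleep counterpart of the 4-h shift case."""
    st = jetlag_state(cycle3, 4.0)
    return minimize_time_controllable(st, 1.0, cycle3, 10000.0, spec3, params,
                                      bins_h=0.5, dt=0.02, resolution=1.0,
                                      max_inner=25,
                                      spontaneous_warm_start=small_spont_result)
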