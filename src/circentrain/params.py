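"""Model parameters for the two-process (circadian + sleep homeostat) models.

All parameters default to the published values of the Jewett-Forger-Kronauer
(JFK) circadian pacemaker model and Achermann's two-process sleep model, in
the units used throughout this package: time in hours, light intensity in lux,
states dimensionless (``x_c`` nominally carries 1/h).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field

__all__ = ["ModelParams", "VARIANTS"]

#: Recognized model variants: full third-order JFK + homeostat, second-order
#: (Process L at steady state) + homeostat, first-order phase model +
#: homeostat, and the circadian-only third-order model without sleep.
VARIANTS = ("S+C3", "S+C2", "S+C1", "C3")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of Process L, Process P, Process S and the sleep automaton.

    Attributes
    ----------
    alpha0, gamma, I0, G, p
        Process L (retinal light transduction): activation rate scale (1/h),
        recovery rate (1/h), reference intensity (lux), drive gain, and the
        intensity exponent.
    mu, q, tau_x, k, k_c
        Process P (core-body-temperature oscillator): van der Pol stiffness
        (1/h), drive coupling terms, and intrinsic period (h).
    omega0
        Free-running angular frequency of the phase-reduced model (rad/h).
    tau_r, tau_d
        Homeostat rise (wake) and decay (sleep) time constants (h).
    H_m, L_m
        Spontaneous sleep-onset and wake thresholds on sleepiness B.
    A_c
        Circadian amplitude weight in the sleepiness B = H - A_c * x.
    B1_max, B2_max
        Upper sleepiness bounds at controllable sleep onsets and wakes.
    """

    alpha0: float = 0.05
    gamma: float = 0.0075
    I0: float = 9500.0
    G: float = 33.75
    p: float = 0.5
    mu: float = 0.13
    q: float = 1.0 / 3.0
    tau_x: float = 24.2
    k: float = 0.55
    k_c: float = 0.4
    omega0: float = field(default=2.0 * math.pi / 24.2)
    tau_r: float = 18.2
    tau_d: float = 4.2
    H_m: float = 0.67
    L_m: float = 0.17
    A_c: float = 0.1333
    B1_max: float = 0.77
    B2_max: float = 0.27

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not (value > 0.0 and math.isfinite(value)):
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value}")
        if not self.L_m < self.H_m:
            raise ValueError("require L_m < H_m (hysteresis band must be non-empty)")
        if not self.H_m <= self.B1_max:
            raise ValueError("require H_m <= B1_max")
        if not self.L_m <= self.B2_max:
            raise ValueError("require L_m <= B2_max")

    @property
    def freq_sq(self) -> float:
        """Squared stiffness frequency term (24 / (0.99729 tau_x))^2 of Process P."""
        return (24.0 / (0.99729 * self.tau_x)) ** 2

    def digest(self) -> str:
        """Short stable hash of the parameter set, used as a cache key."""
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
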