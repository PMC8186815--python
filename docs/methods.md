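# Methods

## Model

The continuous state couples retinal light transduction (Process L), the
core-body-temperature circadian oscillator (Process C) and the sleep
homeostat (Process S):

    dn/dt  = 60 (α(I)(1−n) − γ n),        α(I) = α₀ (I(1−β)/I₀)ᵖ
    u      = G α (1−n)
    dx/dt  = (π/12)[x_c + μ(x/3 + 4x³/3 − 256x⁷/105) + (1−0.4x)(1−k_c x_c) u]
    dx_c/dt= (π/12)[(q x_c − k x)(1−0.4x)(1−k_c x_c) u − (24/(0.99729 τ_x))² x]
    dH/dt  = −H/τ_d (asleep) or (1−H)/τ_r (awake)

with the discrete sleep state β ∈ {0, 1}. Sleepiness B = H − A_c x drives
the spontaneous automaton: sleep at B = H_m rising, wake at B = L_m falling,
hysteresis in between; the factor (1−β) gates light off during sleep, so
light cannot influence any process while the subject sleeps.

Parameter defaults (units h, lux, dimensionless): α₀ = 0.05 /h, γ =
0.0075 /h, I₀ = 9500 lux, G = 33.75, p = 0.5, μ = 0.13 /h, q = 1/3, τ_x =
24.2 h, k = 0.55 /h, k_c = 0.4 h, ω₀ = 2π/24.2 rad/h, τ_r = 18.2 h, τ_d =
4.2 h, H_m = 0.67, L_m = 0.17, A_c = 0.1333, B1_max = 0.77, B2_max = 0.27.
These are the published values of the constituent models; `ModelParams`
validates positivity and threshold ordering. `x_c` nominally carries 1/h
but is treated as a plain state component — no unit conversion anywhere.

Model variants: `S+C3` (full, y = [n, x, x_c, H]), `S+C2` (Process L at its
steady state n = α/(α+γ), u = Gγα/(α+γ); y = [x, x_c, H]), `S+C1`
(phase-reduced, dθ/dt = ω₀ + f(θ)u with tabulated PRC; y = [θ, H]), and
`C3` (circadian-only, no sleep, for light-only entrainment baselines).

## Hybrid integration

Fixed-step classical RK4 with default dt = 0.005 h and steps aligned to the
global dt grid, restarted exactly at light breakpoints, scheduled switch
times and threshold events; sleepiness-threshold crossings are localized by
bisection to 10⁻⁶ h. β is right-continuous; when a switch coincides with a
light breakpoint the switch is processed first so the gating sees the new
β. Adaptive steppers were rejected deliberately: hybrid switching punishes
step-size controllers and fixed steps keep runs bit-reproducible (the whole
pipeline contains no randomness). The factor 60 in the Process L equation
makes n the fastest state (relaxation ≈ 0.7 h under 1000 lux); dt = 0.005 h
resolves it comfortably and dt = 0.02 h (used inside long optimizations) is
still well within the RK4 stability region at 10⁴ lux. Halving dt changes a
48-h trajectory's endpoint by < 10⁻⁵.

## Reference cycles and clock anchoring

The reference subject lives under I_ref(t): 1000 lux for mod(t,24) ∈
[0,16), darkness otherwise, with t = 0 ↔ 6 am. The entrained cycle Y_REF is
found by simulating from a fixed interior initial condition (x=1, x_c=0,
n=0.5, H=0.5, awake) until the state sampled at 24-h intervals moves by
< 10⁻⁸ (max-norm; ~70 days; cap 200 days), then storing one dense period on
a 0.01-h grid with periodic cubic interpolation (smooth reference gradients
for the optimizer). Under the defaults the reference sleeps ≈ 11:10 pm –
7:30 am, so the light actually received is a 14.5 h : 9.5 h cycle; the
circadian-only reference for light-only baselines is computed under that
effective photoperiod. Entrainment targets y_ref(t) = Y_REF(t + Δ_init);
jet-lag runs start at 7 am (Δ_init = 1) with y(0) = y_ref(Δ_shift),
shift-work runs anchor t = 0 to 8 am (Δ_init = 2).

The reduced variants entrain to cycles that sit ~0.7–1.1 h later in phase
than the full model's: the steady-state drive omits the Process L morning
transient (u spikes to ≈ 0.54 at wake before settling at 0.1731), which
feeds the full model's morning phase-advance region every day. The cycles
are therefore asserted *close* (phase offset < 1.5 h) rather than
pointwise equal.

## Phase and PRC

Circadian phase is the two-argument arctangent θ = atan2(−x_c, x) ∈ [0,2π).
The PRC f(θ) is estimated on the second-order model: from each of 256
phases on the free-running limit cycle, apply u = 0.1731 for 0.5 h, let
transients decay for 10 free-running periods (the settling horizon is this
package's choice), and read the asymptotic shift from the offset of upward
zero crossings of x against the unperturbed run, paired to the nearest
crossing and converted with the measured free-running period. f stores
shift per unit drive per hour, so the phase model reproduces the
calibration pulse by construction. Mapped to the reference clock, f > 0
from ≈ 7:30 am to ≈ 5 pm and f < 0 from ≈ 5 pm to ≈ 11:10 pm.

## Terminal condition and entrainment time

φ = ‖[x, x_c, H] − ref‖² − tol for S+C3/S+C2 (n excluded — minutes-scale
transient), ‖[θ, H] − ref‖² − tol with wrapped angular difference for S+C1.
The source study's tol is unpublished; the package default is tol = 0.01 on
the squared norm, exposed in configuration, and all reported entrainment
times use it. Entrainment time is the first φ ≤ 0 crossing (linear
interpolation between integration nodes); for shift work the clock starts
at the end of the shift.

## Optimization

Light is piecewise constant on uniform bins (default 0.1 h; 0.25–0.5 h in
long problems). Each bin carries s = (I/I_max)ᵖ ∈ [0,1], making α affine in
the decision and the gradient finite at darkness (dα/dI → ∞ as I → 0 for
p < 1); reduced variants use s = u/u_max. Gradients of φ(t_f) come from the
co-state λ integrated backward along the stored trajectory (λ̇ = −(∂F/∂y)ᵀλ,
λ(t_f) = ∂φ/∂y) with cubic-Hermite state interpolation at half-steps. At a
state-triggered switch (threshold crossing of B) the co-state jumps by the
first-order variation of the trigger condition,
λ⁻ = λ⁺ − [λ⁺·(F₁−F₂)/(∇B·F₁)] ∇Bᵀ, with a warning-and-skip fallback if
∇B·F₁ ≈ 0; a time-scheduled switch instead contributes the switch-time
gradient λᵀ(F₁−F₂). Gradients over sleep bins are exactly zero (light is
decoupled). Adjoint gradients agree with central finite differences to
< 1% across switches — this comparison is a standing test, not a one-off.

Fixed-horizon descent is projected gradient with Armijo backtracking, no
randomness; controllable sleep adds the switch times as decisions. Switch
times are kept feasible by a guarded schedule: a scheduled sleep is
deferred until B ≥ H_m and forced at B1_max, a scheduled wake deferred
until B ≤ B2_max and forced at L_m — projection onto the sleepiness windows
by construction. Realized wake intervals longer than 18 h are shortened by
re-scheduling the preceding wake earlier (clamped to the B ≤ B2_max
crossing).

The minimum-time outer loop confirms a feasible horizon (open-loop time as
fallback start), then shrinks it by geometric continuation — 8 % of the
horizon per probe, halving the step after a failure, warm-starting each
probe from the previous feasible schedule truncated — down to the requested
resolution (default 0.02 h; 1–2 h in multi-week problems). Plain bisection
between 0 and the feasible horizon was tried first and plateaus far above
the optimum on long problems: a probe at half the horizon leaves the warm
start useless, and because light inside the current sleep window has zero
gradient, light and sleep cannot restructure jointly from a distant start.

For problems longer than 48 h the continuation is additionally seeded with
day-structured maximal-shift candidates: each waking period dark for its
first A hours and maximally lit afterwards (delay mode; reversed for
advance), the sleep automaton at the controllable bounds (0.77/0.17 delay,
0.67/0.27 advance), A ∈ {0, 4, 7, 10}, with a handover to reference light +
spontaneous sleep evaluated at every wake. The best candidate initializes
the descent; all reported optima still come from the adjoint descent and
are thresholded to bang-off {0, I_max} at I_max/2 and re-verified (if the
midpoint cut breaks feasibility, a few quantile cuts are scanned; the
bang-off status is reported in diagnostics).

A light-only optimizer (no Process S) over the circadian-only model serves
as a baseline, with a tuned sleep rule slaving sleep to its optimal light;
reduced-model optima transfer to the full model by I = I_max·u/u_max with
sleepiness-guarded schedule following and a reference-light supplement
phase.

## Feedback controller

Training: run the controllable-sleep optimizer over time-shift cases,
sample each optimal trajectory at Δt = 0.01 h, and store (θ, H, θ_ref) with
the optimal action — light plus a countdown to the next scheduled sleep
while awake, a countdown to the next wake while asleep. Past the last
optimized switch the countdowns continue into the entrained reference sleep
pattern (the subject is entrained at t_f), keeping them defined on every
record. The policy is 1-nearest-neighbor with phases embedded as
(cos, sin) pairs, H unscaled, Euclidean metric, ties to the lowest record
index. Closed loop, the controller is re-queried every 0.1 h (a fresh query
overrides a pending countdown — the policy stays Markov in the measured
state) and countdown-commanded switches pass through the sleepiness
guards. On training cases the closed-loop entrainment time replays the
optimum within ~1 %.

## Problem sizes in the shipped tests

The test suite and the acceptance script state their own scales: reference
cycles and open-loop runs use dt = 0.005 h; the optimized shift-work runs
use 0.25-h bins at dt = 0.005; the multi-week jet-lag optimizations and the
six-case time-shift sweep use 0.5-h bins, dt = 0.02 h and 2-h horizon
resolution; feedback training in tests uses single small shift cases.

## What the simulations do and do not show

All results are properties of the deterministic two-process model with
population-average parameters. The simulations contain no inter-individual
variability, no measurement noise, no spectral light sensitivity (the lux
scalar stands for broad-spectrum light), no REM/NREM structure, and no
photoperiod seasonality (square 16:8 reference light). Passing tests show
the solver and optimizer reproduce the model's published behavior; they say
nothing about how an individual human would respond to the schedules.

## Known limitations

* The optimizer is a local method on a nonconvex problem; the candidate
  family plus continuation recovers the published optima for the cases
  checked, but intermediate time shifts can remain above the true optimum
  (the 12-h shift at 10⁴ lux stalls ~20 % high), so the sweep-shaped
  asymmetry claim is asserted on the spontaneous-sleep curve.
* The 18-h maximum-wake constraint is enforced by projection; in a minority
  of coarse sweep cases the sleepiness windows and the current light
  pattern pin every switch time and one ~19-h wake interval survives. The
  sleepiness bound constraints themselves are satisfied exactly in all
  reported schedules.
* Entrainment times inherit the terminal tolerance choice (tol = 0.01);
  values quoted to hundredths of an hour are tolerance-dependent at about
  the percent level.
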