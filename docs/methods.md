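# Methods

## The measurement chain being modelled

A whole-cell voltage-clamp experiment never applies the commanded voltage
directly to the membrane.  Between the amplifier and the cell sit a series
resistance R_s (pipette tip + access), the cell membrane capacitance C_m, a
parasitic pipette/well-plate capacitance C_p, a net voltage offset V_off
(electrode offsets, junction potentials), and a seal leak of conductance
g_leak ≈ 1/R_seal.  Amplifiers *partially* compensate these: an offset
correction V_off\*, C-fast and C-slow circuits that inject the estimated
capacitive currents (C_p\*, C_m\*) so they never reach the current meter,
and series-resistance compensation that boosts the applied potential by a
requested fraction α (typically 0.7–0.85) of the estimated R_s voltage
drop.  What survives the compensation — the *residuals*, marked with a
dagger (V_off†, g_leak†) — distorts the recorded current.

The package models this chain at three levels of realism around a plug-in
membrane-current model (a two-gate Hodgkin–Huxley I_Kr, a Type I model
cell = pure membrane resistor, or a Type II model cell = resistor plus an
R_k–C_k branch giving ~100 ms current kinetics).

### Ideal clamp

V_m ≡ V_cmd and I_out ≡ I_ion.  Only the cell states are integrated.

### Full experiment model

State vector [V_m, V_p, V_clamp, I_out, V_est] plus cell states (V_est is
the C-slow circuit's internal estimate of the membrane voltage):

    I_Rs      = (V_p + V_off − V_m) / R_s
    C_m dV_m  = I_Rs − I_cell − g_leak (V_m − E_leak)
    dV_p      = (V_clamp − V_p) / τ_clamp
    I_cs      = (V_clamp − V_est) / R_s*,   dV_est = I_cs / C_m*
    dV_clamp  = (V_cmd − V_off* + α R_s* (I_out + I_cs) − V_clamp) / τ_sum
    I_in      = (C_p − C_p*) dV_p + I_Rs − I_cs
    dI_out    = (I_in − I_out) / τ_z

Sign convention: outward membrane current positive; V_off enters once, as
a pipette-side offset added to the applied potential.  The equations are
derived from the standard resistive-feedback headstage circuit under the
assumption of ideal operational components.  One genuinely open design
point is whether the R_s-compensation loop is driven by the measured
current alone or by the total estimated access current (measured current
plus the C-slow injection, i.e. with supercharging/prediction).  This
package uses the latter: it is what makes the full model reduce *exactly*
to the simplified model in the fast-amplifier limit, and it reproduces the
intended behaviour that α = 1 with accurate estimates clamps V_m to
V_cmd + V_off†.  Because the equations are derived rather than copied,
their correctness is enforced by independent oracles in the test suite:
a Kirchhoff DC-circuit solver (2×2 linear system written from the circuit,
not from the model), charge conservation of uncompensated capacitive
spikes (∫I dt = C_p ΔV), the exponential-relaxation closed forms of each
linear sub-circuit, and the limiting equivalences below.

### Simplified experiment model

For currents as slow as I_Kr the amplifier time constants (τ_clamp
0.8 µs, τ_z = R_f C_f = 7.5 µs, τ_sum ~tens of µs) are effectively
instantaneous, the capacitive artefacts are compensated away, and the
machine estimates C_m\*, R_s\* track the true values.  The state then
collapses to V_m plus cell states:

    R_eff    = R_s − α R_s*          (effective access resistance)
    I_Rs     = (V_cmd + V_off† − V_m) / R_eff
    C_m dV_m = I_Rs − I_ion − g_leak† (V_m − E_leak†)
    I_out    = I_post = I_ion + g_leak† (V_m − E_leak†)

The model lives downstream of the primary leak subtraction: g_leak† is
the *residual* leak left by an imperfect linear subtraction performed at
V_cmd while the physical leak follows V_m, and E_leak† is pinned at the
holding potential (−80 mV) because the primary subtraction zeroes the
current there.  Hence I_out and I_post coincide inside this model, while
`subtract_leak` produces I_post = I_out − g\*(V_cmd − E\*) on recordings.
At α = 1 with R_s\* = R_s the access resistance vanishes and
V_m = V_cmd + V_off† holds algebraically; the implementation switches to
that analytic branch below R_eff = 1e−9 GΩ rather than integrating a
singular ODE.  Driving α R_s\* above R_s is rejected (a real amplifier
oscillates there).

Two structural facts worth noting, both tested: the steady-state voltage
error obeys V_cmd + V_off† − V_m = R_eff·I, so the series-resistance
artefact grows in proportion to the current; and compensation at α shrinks
the per-pA voltage error by exactly 1/(1−α).

## I_Kr model

I = g_Kr · a · r · (V_m − E_K), with gates relaxing as
da/dt = (a∞ − a)/τ_act, a∞ = k1/(k1+k2), τ_act = 1/(k1+k2) (and the
analogous r equations on k3, k4), where k1 = p1 e^{p2 V}, k2 = p3 e^{−p4 V},
k3 = p5 e^{p6 V}, k4 = p7 e^{−p8 V}.  All nine parameters are strictly
positive; E_K comes from the Nernst equation (−85.2 mV at K_o = 4 mM,
K_i = 110 mM, 25 °C).  The default parameter set is a documented
placeholder with representative room-temperature hERG1a magnitudes
(activation τ ≈ 3.9 s at 0 mV, inactivation-recovery τ ≈ 11 ms); fitted
values for a specific dataset are loadable inputs, not constants, and no
test depends on the placeholder's exact values.  The field's older
convention of quoting p-parameters in s⁻¹ / V⁻¹ is converted at the file
I/O boundary (round-trip tested); internally everything is ms, mV, GΩ,
pF, pA, nS, so R·C is in ms and nS·mV = pA.  The symbol clash between the
activation time constant and the access time constant R_s C_m is resolved
by naming them `tau_act` and `tau_access`.

## Numerics

Three integration engines, cross-validated against each other:

* **expm** (default for model cells): the circuit + model-cell system is
  linear time-invariant with a piecewise-linear input, so each protocol
  segment is propagated exactly by the matrix exponential of an augmented
  system; within a segment the regular sampling grid is evaluated in one
  shot through the eigendecomposition of the one-step map (with a
  sequential fallback when the map is ill-conditioned).  Machine-precision
  and ~20 ms for a 15 s staircase.
* **split** (default for I_Kr under ideal/simplified clamps): fixed
  substeps (default 0.05 ms) combining Rush–Larsen exact exponential gate
  updates with an exact exponential step of the conditionally-linear V_m
  equation (given the gates, the I_Kr current is ohmic, so the V_m ODE is
  linear within a substep).  Unconditionally stable, so the sub-ms access
  time constant C_m R_eff does not limit the step; numba-compiled.
  Agreement with the reference engine is ~2×10⁻⁴ relative L2 on fixture
  protocols, far below the noise level and the recovery tolerances.
* **scipy** (reference, any model): `solve_ivp` (LSODA or BDF) on the
  exact right-hand sides, integrated segment by segment with
  re-initialisation at step discontinuities (segments are left-closed,
  right-open, so boundary values are deterministic).  Defaults rtol 1e−8,
  atol 1e−10; halving tolerances moves a Type II staircase trace by
  <10⁻⁶ RMS.

Initial conditions are the steady state at the holding potential (exact
linear solve for model cells; damped fixed-point iteration on the DC
balance for I_Kr).

## Leak estimation

`estimate_leak` fits I = g(V_cmd − E) by least squares over a commanded
voltage-ramp window (the fixtures include the −120 → −80 mV ramp), then
re-solves E from the measured mean holding current so that g(holding − E)
reproduces it — the "zero current at holding" convention.  For exactly
linear data the adjustment returns the fitted E unchanged; for noisy data
the estimator follows ordinary least-squares theory (tested against the
analytic standard errors).  A zero-current trace returns g\* = 0 with
E\* = holding and a `degenerate` flag, since E is then unidentifiable.

## Synthetic populations

`draw_population` emulates a multi-well plate in which every cell shares
the kinetic vector θ but draws its own conductance and artefacts:
conductance log-normal (median 30 nS, log-sd 0.4), V_off† normal
(0 ± 2 mV, keeping draws within ≈ ±5 mV), g_leak† half-normal (scale
0.2 nS, far below the median conductance), α uniform on 0.70–0.85, C_m
uniform on 5–20 pF, R_s uniform on 5–20 MΩ, C_p uniform on 3–5 pF, with
the machine estimates C_m\*, R_s\* taken as accurate.  Measurement noise
is iid Gaussian on I_out, default 5 pA — a declared simplification, since
the real instrument's noise spectrum is unpublished.  Each cell uses a
random stream keyed by (master seed, cell index), so populations extend
without reshuffling and datasets regenerate bit-identically.  Model-cell
fixture recordings use the reference hardware values C_p = 4.7 pF,
R_s = 30 MΩ, C_m = 22 pF, R_m = 500 MΩ, C_k = 1000 pF, R_k = 100 MΩ
(τ_k = 100 ms), V_off = 0.

What the generator does *not* emulate: pharmacological subtraction,
well-to-well temperature or solution differences, seal loss and other
quality-control failures, correlated or 1/f noise.  Passing recovery tests
therefore show that the inference machinery is correct and well-posed
under the model's own assumptions, not that the model is free of
discrepancy on real cells — indeed the known failure signature on real
data (series resistance estimated at its imposed bound) is kept as a
mandatory `bound_hit` diagnostic on every fit.

## Fitting

The objective is the sum of squared model–data current differences (its
negation is the Gaussian log-likelihood up to a constant).  Searches run
in a transformed unit box: strictly positive parameters (conductances,
base rates p1/p3/p5/p7, resistances, capacitances, residual leak) on a log
scale, voltage sensitivities p2/p4/p6/p8 and offsets on the identity scale
with positivity/box bounds (sensitivities capped at 0.2 mV⁻¹ so the
midpoint start is admissible).  Parameter sets whose rates leave
[1.67×10⁻⁵, 10³] ms⁻¹ at the voltage where each rate is largest are
rejected with an infinite objective: they imply unresolvably fast or
frozen gating.

The global optimizer is an in-package CMA-ES (standard (µ/µ_w, λ)
formulation with cumulative step-size adaptation and rank-one/rank-µ
covariance updates; λ defaults to 4 + ⌊3 ln n⌋).  Out-of-box candidates
are repaired by clipping and penalised quadratically on the repair
distance, so returned solutions always respect the bounds.  Fits start at
the unit-box midpoint, use seeded restarts from perturbed midpoints, and
finish with a bounded trust-region least-squares polish.  Everything is
deterministic given the seed.  `FitResult.bound_hit` flags any parameter
within 10⁻³ (unit-box distance) of a bound.

The shared-kinetics scheme (`fit_shared`) alternates: one CMA-ES
generation proposes θ candidates; each candidate is scored by optimising
every cell's {g, V_off†, g_leak†} — warm-started from the incumbent's
per-cell optima, which cannot worsen the accept-if-better outer step —
and the incumbent (θ, per-cell parameters) is replaced only when the
total objective improves, making the outer trace monotone non-increasing.
After outer convergence (stall counter or relative improvement < 10⁻⁶) a
single joint least-squares refinement over (θ, all per-cell parameters)
sharpens the optimum, again accepted only if better.  With N = 1 the
scheme degenerates to a single-cell fit of the same objective.

## Problem sizes and budgets

The desk-scale experiments use the ~14.5 s staircase-like fixture sampled
at 1 ms, N = 5 cells for the shared fit and the hypothesis comparison,
CMA-ES budgets of 120–200 generations with 1–2 restarts for single-cell
fits and 25 outer generations for the shared fit.  These sizes were chosen
so the full validation pipeline completes on a single CPU while leaving
comfortable identifiability margins; all of them are configurable.

## Known limitations

* The staircase and action-potential fixtures are envelope-faithful
  stand-ins, not replicas of the published protocol tables; exact
  protocols can be loaded from segment files.
* Model-cell component fitting uses a dedicated calibration protocol
  (`model_cell_calibration`: steps with 2 ms ramp edges, 0.2 ms sampling,
  holding 0 mV).  On a 1 ms-sampled staircase the capacitive transients
  (τ_z = 7.5 µs) fall between samples and C_p is close to unidentifiable;
  finite-slope edges give C_p a sustained ~100 pA signature, mirroring how
  the hardware experiments expose the capacitances through transients.
* The full model with an I_Kr cell integrates through the scipy engine
  only (7 stiff states spanning ~7 decades of timescales); it is intended
  for model cells and small studies, mirroring the documented workflow of
  fitting biological data with the simplified model.
* White measurement noise and noise-free V_m traces are simplifications.
* The amplifier's own estimation routines (test-pulse fits) are not
  emulated; machine settings are inputs.
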