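# vclamp

Mathematical models of the *whole* voltage-clamp experiment — not just the
ion current, but the series resistance, membrane and pipette capacitance,
voltage offsets, the amplifier circuitry that imperfectly compensates
them, and imperfect leak subtraction — together with inference schemes
that fit current models *through* this measurement chain.

The package is for cardiac/ion-channel electrophysiologists and modellers
who calibrate Hodgkin–Huxley-style current models (here: a two-gate
hERG/I_Kr model) to whole-cell patch-clamp data, and who need to know how
much of the cell-to-cell variability in fitted kinetics is real biology
versus patch-clamp artefact.  It implements:

* **Clamp models.**  An ideal clamp (V_m ≡ V_cmd, I_out ≡ I_ion); a full
  experiment model whose state [V_m, V_p, V_clamp, I_out, V_est] tracks
  the pipette and clamp potentials, the slow current readout
  (τ_z = R_f C_f) and the C-slow compensation estimate, with
  fractional series-resistance compensation α; and a simplified model for
  slow currents in which the amplifier is algebraic and only the residual
  offset V_off† and residual leak g_leak† survive:

      C_m dV_m/dt = (V_cmd + V_off† − V_m)/(R_s − α R_s*)
                    − I_ion − g_leak† (V_m − E_leak†)

* **Cell models.**  I_Kr: I = g_Kr·a·r·(V_m − E_K) with
  da/dt = (a∞ − a)/τ_a, a∞ = k1/(k1+k2), k1 = p1 e^{p2 V_m}, … ; plus
  Type I (R_m) and Type II (R_m ∥ R_k–C_k, τ_k = R_k C_k = 100 ms)
  electrical model cells for amplifier validation.

* **Leak handling.**  I_leak\* = g\*(V_cmd − E\*) estimated on a
  −120→−80 mV ramp with the zero-current-at-holding convention, and
  I_post = I_out − I_leak\*.

* **Synthetic data.**  Ground-truthed multi-well populations with shared
  kinetics θ and per-cell conductance + artefacts (the generative picture
  in which variability is experimental, not biological).

* **Inference.**  CMA-ES fits in log/identity-transformed bounded space:
  single-cell fits (kinetics-only; kinetics + artefacts; model-cell
  components) and a nested shared-kinetics fit in which one θ is optimised
  for all N cells while each cell keeps {g_i, V_off†_i, g_leak†_i}, with a
  monotone accept-if-better outer loop.  At N = 124 cells the
  cell-specific-kinetics hypothesis carries 9×124 = 1116 parameters, the
  shared-kinetics hypothesis 8 + 3×124 = 380 — 736 fewer.

* **Metrics.**  RRMSE = ‖I_model − I_data‖₂ / ‖I_data‖₂, per-protocol
  best/median/90th-percentile summaries, and hypothesis-comparison tables.

## Worked example

Simulate an uncompensated Type I model cell (R_m = 500 MΩ) held at
+100 mV through R_s = 30 MΩ, then the same cell with α = 80% series
resistance compensation:

```python
import vclamp
from vclamp.protocol import Protocol, Segment

p = Protocol((Segment(1000.0, 100.0, 100.0),), dt=2.0, holding=0.0)
cell = vclamp.ModelCellTypeI(R_m=0.5)
art = vclamp.ArtefactTrue(C_p=4.7, C_m=22.0, R_s=0.03)

raw = vclamp.simulate(p, "full", cell, artefact=art,
                      machine=vclamp.MachineSettings())
comp = vclamp.simulate(p, "full", cell, artefact=art,
                       machine=vclamp.compensated_settings(art, alpha=0.8))
print(f"uncompensated: I_out = {raw.i_out[-1]:.2f} pA, "
      f"V_m = {raw.v_m[-1]:.2f} mV")
print(f"alpha = 0.8:   I_out = {comp.i_out[-1]:.2f} pA, "
      f"V_m = {comp.v_m[-1]:.2f} mV")
```

prints

```
uncompensated: I_out = 188.68 pA, V_m = 94.34 mV
alpha = 0.8:   I_out = 197.63 pA, V_m = 98.81 mV
```

Uncompensated, the cell sees only 94.34 mV of the commanded 100 mV — the
voltage divider R_m/(R_s + R_m) = 0.943 at work, with
I_out = 100/(0.03 + 0.5) = 188.68 pA.  Compensation boosts the applied
potential and recovers most of the drop: the error per pA of current
shrinks by exactly 1/(1 − α) = 5.

A synthetic population with shared kinetics and per-cell artefacts:

```python
from vclamp.synthetic import PopulationHyperparameters, draw_population, \
    generate_dataset

h = PopulationHyperparameters(N=5, noise_sd=5.0)
truth = draw_population(h, seed=1)        # per-cell g, V_off†, g_leak†, ...
recs = generate_dataset(truth, vclamp.fixtures()["staircase_like"], seed=1)
```

`vclamp.fit_shared(recs, protocol, ...)` then recovers the shared θ and
every cell's artefact parameters from those recordings alone; see
`docs/methods.md` for the scheme and its guarantees.

There is also a thin CLI (`vclamp simulate|synth|leak-subtract|fit|
fit-shared|compare|report`) over the same library.

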