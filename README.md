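# knobsim

Hands-on, closed-loop parameter exploration for a conductance-based neuron
model. Instead of an automated optimizer with a hand-crafted error function,
the workflow is the one a synthesizer player uses: every knob or slider
movement on a control surface (a MIDI device, or a deterministic scripted
stand-in) remaps into model-parameter units, immediately reruns the
simulation, and gets recorded in a replayable session log. The package is
aimed at computational neuroscientists and instructors who want to *feel*
how a model's parameters shape its behavior — and to be able to reproduce,
exactly, the tuning journey that led to an interesting regime.

## The model

A single-compartment membrane with transient sodium, delayed-rectifier
potassium and leak currents:

    C_m dV/dt = -ḡ_Na m³h (V - E_Na) - ḡ_K n⁴ (V - E_K) - g_L (V - E_L) + I(t)

Two modifications make the kinetics directly knob-controllable:

- each gating variable x ∈ {m, h, n} relaxes toward a **sigmoidal steady
  state** x∞(V) = 1 / (1 + exp(−(V − μ_x)/s_x)), so one control shifts the
  activation curve (μ_x, mV) and another tilts it (s_x, mV; a negative s_h
  makes inactivation close with depolarization);
- the **time constants τ_m, τ_h, τ_n are voltage-independent** and
  user-controlled.

That gives eleven live parameters (τ_m, τ_h, τ_n, μ_m, μ_h, μ_n, s_m, s_h,
s_n, ḡ_Na, ḡ_K) plus the step-current amplitude I — twelve control elements
in the stock session. Integration is semi-implicit: explicit Euler for the
gating variables, implicit (backward) Euler for the voltage, which stays
finite at arbitrarily coarse time steps. The default protocol is a 300 ms
run at Δt = 0.1 ms with a current step from t = 50 ms to t = 250 ms.

## Worked example

Replay the bundled tuning journey that starts from the regular-spiking
baseline and dials the sodium-inactivation knobs until the cell only fires
at stimulus onset:

```
$ knobsim run --config src/knobsim/data/fitting_config.yaml \
              --script src/knobsim/data/fit_transient_spiking.csv \
              --output-dir demo_out
simulations: 7 (1 baseline + 6 event-driven)
skipped events: 0
final spike count: 1
artifacts in demo_out/
```

Seven simulations ran: one baseline plus one per applied knob event. The
final trace has a single spike — firing confined to stimulus onset, because
the journey moved the inactivation midpoint to −70 mV, steepened its slope
and slowed its recovery (τ_h ≈ 15 ms). `demo_out/` contains the replayable
`session_log.json`, the final voltage trace, and the per-event trajectory:

```
sim_index,element_id,parameter,raw_value,mapped_value
1,11,I_amp,42,9.921259842519685
2,4,mu_h,60,-66.37795275590551
...
```

One-shot runs work from presets; three ship with the package
(`regular_spiking`, `subthreshold_oscillations`, `transient_spiking`):

```
$ knobsim simulate --preset subthreshold_oscillations --trace-out sub.csv
spikes: 0
regime: subthreshold_oscillations
trace written to sub.csv
```

Other subcommands: `replay` (re-execute a session log and fail loudly if it
diverges), `plot` (parameter trajectories, raw 0–127 value vs simulation
index), `presets`, and `make-fixture` (seeded random event scripts).

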