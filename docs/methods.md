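# Methods

## Model

The simulated cell is a single isopotential compartment with transient
sodium, delayed-rectifier potassium and leak currents:

    C_m dV/dt = −ḡ_Na m³h (V − E_Na) − ḡ_K n⁴ (V − E_K) − g_L (V − E_L) + I(t)
    dx/dt = (x∞(V) − x) / τ_x ,   x ∈ {m, h, n}
    x∞(V) = 1 / (1 + exp(−(V − μ_x)/s_x))

Assumptions that distinguish this variant from the classic rate-constant
formulation:

- **Sigmoidal steady states.** Each activation curve is a plain logistic in
  V, so it can be shifted (μ_x) and tilted (s_x) with one control each.
  The slope factor carries the gating direction in its sign: s_m, s_n > 0
  (activation opens with depolarization), s_h < 0 (inactivation closes
  with depolarization). No separate direction flag exists; flipping the
  sign of any s_x flips that gate's character.
- **Voltage-independent time constants.** τ_m, τ_h, τ_n are constants under
  user control, not functions of V. This removes the bell-shaped τ(V)
  profiles of the classic model; consequences are discussed under
  Limitations.
- **Classic current balance.** The m³h and n⁴ exponents and the constants
  C_m = 1 µF/cm², E_Na = 50 mV, E_K = −77 mV, E_L = −54.4 mV,
  g_L = 0.3 mS/cm² are the textbook squid-axon values (all overridable in
  any parameter file); only the eleven kinetics/conductance parameters are
  treated as live tunables.
- **Current units.** The injected step is treated as a current *density* in
  µA/cm², consistent with C_m in µF/cm². A point compartment is scale-free
  up to this convention: reading the amplitude as nA simply rescales the
  implied membrane area.

## Numerics

**Semi-implicit update.** Within one step of size Δt, the gating variables
advance first with explicit Euler evaluated at the *old* voltage, then the
voltage advances with backward Euler using the freshly updated
conductances:

    x ← clamp(x + Δt (x∞(V_old) − x)/τ_x, 0, 1)
    V ← (C_m V/Δt + g_Na E_Na + g_K E_K + g_L E_L + I) / (C_m/Δt + g_Na + g_K + g_L)

Because the implicit update is a convex combination of V and the effective
reversal potential (shifted by I), the voltage cannot overshoot the hull of
the reversal potentials at I = 0 and remains finite for any Δt. The
acceptance script demonstrates this at Δt = 10 ms, where a fully explicit
voltage update diverges on the same parameter set.

**Gating clamp.** The explicit gating step can only leave [0, 1] when
Δt > τ_x, which a user can cause mid-session by dialing a time constant
below the step size. The update clamps and counts rather than erroring
(the trace carries a `clamp_hits` counter); with Δt below every τ the
counter is asserted to stay zero.

**Stimulus timing.** I(t) = I_amp on the half-open window [t_on, t_off),
evaluated at the start of each step interval, so the boundary sample is not
counted twice. The trace has ⌊duration/Δt⌋ + 1 samples (with a small
tolerance in the floor to absorb binary rounding of Δt).

**Initial state.** By default the run starts at the fixed point of the full
system at I = 0, found by damped iteration (V moves halfway toward the
conductance-weighted balance voltage each round, 2000 rounds max,
tolerance 1e−12); if the iteration does not settle — intrinsically
oscillatory parameter sets have no stable rest — it falls back to E_L.
Gating always starts at steady state for the initial voltage. This avoids
an artificial onset transient before the stimulus.

**Spike detection.** Upward crossings of a 0 mV threshold
(V[i−1] < θ ≤ V[i]), reported at sample i, no refractory window. Standard,
and sufficient for the qualitative regime classification.

**Lookup tables.** `build_lut` tabulates a sigmoid on 2048 points over
[−100, 50] mV with linear interpolation (edge-clamped outside the range);
the interpolation error is below 1e−4 across the range. `simulate`
optionally routes the steady-state evaluations through such tables — the
classic trick for shaving per-step cost — at the price of that bounded
interpolation error.

**Verification.** The integrator is checked against two independent
routes: the closed-form RC step response with both active conductances
off (error under 1 % of the step amplitude, confirmed under step halving),
and a high-accuracy adaptive solve (`scipy.solve_ivp`, LSODA,
rtol 1e−10) of a brute-force restatement of the same ODEs at Δt = 1 µs
over a 50 ms window: subthreshold voltage agrees to well under 0.5 mV and
spike times to ~3 µs.

## Control layer

**Events.** A backend yields `(element ID, raw value)` tuples with raw
values in the 7-bit MIDI data-byte range 0–127; a strictly increasing
sequence counter orders them. The virtual backend replays a CSV script
deterministically (out-of-range values and non-increasing sequence numbers
are rejected at load time); the live MIDI backend translates
control-change messages 1:1 and is optional, requiring hardware and the
`mido` extra — it is not part of the automated test surface.

**Polling.** `poll` drains everything since the last call, in arrival
order. Coalescing (keep only the latest value per element) is off by
default — the per-event simulation trajectory is itself an artifact worth
preserving — but available for models too slow to keep up with a fast
hand. A closed backend raises a distinct error rather than returning an
empty batch.

**Mapping.** A binding maps raw position r ∈ 0..127 into parameter units
either linearly, low + (r/127)(high − low), or exponentially,
low·(high/low)^(r/127) (requires low > 0; used for time constants and
conductances, which span orders of magnitude). Both endpoints are returned
exactly (endpoint-corrected rather than trusting floating-point identity),
and `unmap` inverts the map to the nearest raw step, round-tripping all
128 positions exactly.

**Meta-elements.** A binding may name meta elements that reshape its
interval live on an exponential scale. The law chosen here: a meta
position maps to a factor f between ×1/4 and ×4 with a neutral detent at
raw 64; the two half-ranges use exponents (raw−64)/63 above and
(raw−64)/64 below the detent so that all three anchor positions (0, 64,
127) land exactly on 1/4, 1 and 4. A shared low+high meta rescales the
width about the interval center; a low-only (high-only) meta moves that
bound relative to the opposite one by the same factor. Factors are always
applied to the binding's *base* interval, so a meta knob's position — not
its event history — determines the live bounds. After any meta event the
primary parameter is re-derived from the primary element's last raw
position under the new interval (initialized by unmapping the starting
parameter value). The ×4 full-range span is a package convention,
declared in config and easy to change.

**Default layout and bindings.** The bundled layout emulates a UC-33-class
surface: 33 continuous elements (IDs 0–23 knobs, 24–32 sliders) and 14
buttons (IDs 33–46); the contiguous ID assignment is a package convention.
The stock session binds 12 elements: the eleven model parameters plus the
stimulus amplitude.

## Session loop and replay

A session runs one baseline simulation, then loops: poll, apply each event
(primary mapping, meta reshaping, or bank switch), rerun the model once per
applied event, append one trajectory record carrying the simulation index.
Unbound-element events are logged and skipped; button presses (raw 127)
on configured bank buttons swap the active binding table and neither
simulate nor record. Wall-clock timestamps are recorded but carry no
semantics — only sequence order and simulation index do.

Replay routes the recorded raw values through the *same* engine code path
the live loop used, starting from the log's initial snapshot, then verifies
the resulting parameter vector against the log's final snapshot before
returning the final trace. Since the integrator is deterministic, live and
replayed final traces are bit-identical; the suite asserts this over
scripted and seeded-random sessions, and the acceptance script over 100
random sessions.

## Regime presets and classification

The three bundled presets were found by scripted exploration of this
implementation and frozen in `src/knobsim/data/*.yaml` together with the
features their traces must show:

- **regular_spiking** — the package defaults (ḡ_Na = 120, ḡ_K = 36
  mS/cm², τ_m = 0.3 ms, τ_h = 6 ms, τ_n = 5 ms, μ_m = −40, μ_h = −62,
  μ_n = −53 mV, s_m = 9, s_h = −7, s_n = 15 mV) at I = 10 µA/cm²: tonic
  firing across the stimulus window (12 spikes at the stock step).
- **transient_spiking** — same, but inactivation sits deeper and recovers
  slowly (μ_h = −70 mV, s_h = −4 mV, τ_h = 15 ms): a single onset spike
  shuts the sodium conductance down for the rest of the step.
- **subthreshold_oscillations** — a persistent-sodium/slow-potassium
  resonator: weak low-threshold Na (ḡ_Na = 1 mS/cm², μ_m = −50, s_m = 6),
  inactivation parked near 1 (μ_h = +20 mV), slow steep K
  (ḡ_K = 15 mS/cm², μ_n = −52, s_n = 8 mV, τ_n = 6 ms) at I = 3 µA/cm²:
  zero spikes, sustained membrane oscillations riding the depolarization.

The classifier's thresholds are package conventions, declared per preset
and overridable: regular spiking needs ≥ 5 spikes with the last in the
final third of the stimulus window; transient spiking needs ≥ 1 spike with
all spikes within 50 ms of onset; subthreshold oscillation needs zero
spikes and ≥ 2 local maxima at least 1 mV above the post-transient mean
(the mean voltage over the second half of the stimulus window). Everything
else is "other". All three presets keep their label when the time step is
halved to 0.05 ms, so the regimes are not integration artifacts.

Each preset also ships a recorded tuning journey (`fit_<regime>.csv`
against `fitting_config.yaml`) that reaches its regime from the
regular-spiking baseline; the subthreshold journey exercises a meta knob to
widen the μ_h range beyond its stock bounds.

## What the virtual controller does and does not emulate

The scripted backend reproduces the *contract* of a hardware surface —
ordered 7-bit (ID, value) tuples delivered on poll — exactly and
deterministically. It does not emulate hardware timing: event jitter,
polling latency, or the interleaving of hand movement with simulation
runtime. Passing tests therefore demonstrate correctness of the mapping,
bookkeeping and replay machinery, not the interactive latency experience;
latency on real hardware depends on the host and is out of scope.

## Problem sizes

The stock protocol is 3001 samples (300 ms at 0.1 ms). The test suite and
acceptance script run the oracle comparison at Δt = 1 µs over 50 ms
(50 001 samples), the replay-fidelity check over 100 random 12-event
sessions at the stock protocol, and exhaustive 128-position round-trips
for both map kinds; the full suite completes in well under a minute on one
core.

## Limitations

- Voltage-independent time constants cannot reproduce behaviors that hinge
  on the classic bell-shaped τ(V) (e.g. exact spike shapes of the original
  formulation); that flexibility is deliberately traded for direct control.
- One compartment, three currents, no noise: no morphology, no channel
  stochasticity, no adaptation currents beyond what h and n provide.
- The classifier is intentionally coarse — qualitative regime labels, not
  spike-train statistics; parameter sets near a regime boundary may
  legitimately read "other".
- Automated parameter search is out of scope by design; the package is the
  manual, closed-loop alternative.
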