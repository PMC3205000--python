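# Session config used to record the bundled fit_<regime>.csv journeys.
# Stock 12-element HH binding table; knob 16 acts as a range meta-element
# for the sodium-inactivation midpoint so the knob's reach can be widened
# live (needed to park h near 1 for the subthreshold-oscillation regime).
layout: uc33
backend: "virtual:"
coalesce: false
protocol:
  dt: 0.1
  duration: 300.0
  I_amp: 10.0
  t_on: 50.0
  t_off: 250.0
bindings:
  - {element_id: 0, parameter: tau_m, map_kind: exponential, low: 0.05, high: 10.0}
  - {element_id: 1, parameter: tau_h, map_kind: exponential, low: 0.5, high: 50.0}
  - {element_id: 2, parameter: tau_n, map_kind: exponential, low: 0.5, high: 50.0}
  - {element_id: 3, parameter: mu_m, map_kind: linear, low: -60.0, high: -20.0}
  - {element_id: 4, parameter: mu_h, map_kind: linear, low: -90.0, high: -40.0, meta_high_id: 16}
  - {element_id: 5, parameter: mu_n, map_kind: linear, low: -80.0, high: -30.0}
  - {element_id: 6, parameter: s_m, map_kind: linear, low: 1.0, high: 20.0}
  - {element_id: 7, parameter: s_h, map_kind: linear, low: -20.0, high: -1.0}
  - {element_id: 8, parameter: s_n, map_kind: linear, low: 1.0, high: 25.0}
  - {element_id: 9, parameter: gNa_max, map_kind: exponential, low: 1.0, high: 300.0}
  - {element_id: 10, parameter: gK_max, map_kind: exponential, low: 1.0, high: 200.0}
  - {element_id: 11, parameter: I_amp, map_kind: linear, low: 0.0, high: 30.0}
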