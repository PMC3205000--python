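# Spiking only at stimulus onset: sodium inactivation sits deeper
# (mu_h = -70 mV, steep) and recovers slowly (tau_h = 15 ms), so the first
# spike(s) shut the sodium conductance down for the rest of the step.
name: transient_spiking
parameters:
  tau_m: 0.3
  tau_h: 15.0
  tau_n: 5.0
  mu_m: -40.0
  mu_h: -70.0
  mu_n: -53.0
  s_m: 9.0
  s_h: -4.0
  s_n: 15.0
  gNa_max: 120.0
  gK_max: 36.0
  C_m: 1.0
  E_Na: 50.0
  E_K: -77.0
  E_L: -54.4
  gL: 0.3
protocol:
  dt: 0.1
  duration: 300.0
  I_amp: 10.0
  t_on: 50.0
  t_off: 250.0
expected_features:
  regime: transient_spiking
  min_spikes: 1
  max_spikes: 3
criteria: {}
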