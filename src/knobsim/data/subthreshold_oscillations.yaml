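# No spikes; sustained membrane oscillations from a weak low-threshold
# sodium amplifier (h parked near 1 by the high inactivation midpoint)
# working against a slow, steep potassium recovery.
name: subthreshold_oscillations
parameters:
  tau_m: 0.3
  tau_h: 5.0
  tau_n: 6.0
  mu_m: -50.0
  mu_h: 20.0
  mu_n: -52.0
  s_m: 6.0
  s_h: -7.0
  s_n: 8.0
  gNa_max: 1.0
  gK_max: 15.0
  C_m: 1.0
  E_Na: 50.0
  E_K: -77.0
  E_L: -54.4
  gL: 0.3
protocol:
  dt: 0.1
  duration: 300.0
  I_amp: 3.0
  t_on: 50.0
  t_off: 250.0
expected_features:
  regime: subthreshold_oscillations
  min_spikes: 0
  max_spikes: 0
  min_oscillation_peaks: 2
criteria: {}
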