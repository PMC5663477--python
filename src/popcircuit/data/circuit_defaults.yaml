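# Default L2/3 barrel-cortex circuit parameters.
# Voltages in mV, resistances in MOhm, times in ms, PSP amplitudes in mV
# (inhibitory amplitudes are magnitudes of hyperpolarizing PSPs).
populations:
  E:    {n: 1700, vrest: -68.0, vth: -38.0, rin: 160.0, tref: 55.5, taum: 28.0, tausyn_e: 2.0, tausyn_i: 40.0, erev_i: -68.0}
  Ipv:  {n: 70,   vrest: -68.0, vth: -37.4, rin: 100.0, tref: 5.4,  taum: 21.0, tausyn_e: 2.0, tausyn_i: 16.0, erev_i: -68.0}
  I5ht: {n: 115,  vrest: -62.0, vth: -36.0, rin: 200.0, tref: 21.3, taum: 10.0, tausyn_e: 2.0, tausyn_i: 40.0, erev_i: -62.0}
  Isom: {n: 45,   vrest: -57.0, vth: -40.0, rin: 250.0, tref: 20.0, taum: 30.0, tausyn_e: 2.0, tausyn_i: 40.0, erev_i: -57.0}
n_l4: 1500
erev_e: 0.0
connections:
  EL4:
    E:    {pcon: 0.15,  prel: 0.25, w_mean: 0.8,  w_median: 0.48}
    Ipv:  {pcon: 0.15,  prel: 0.25, w_mean: 0.8,  w_median: 0.48}
    I5ht: {pcon: 0.0}
    Isom: {pcon: 0.15,  prel: 0.25, w_mean: 0.8,  w_median: 0.48}
  E:
    E:    {pcon: 0.17,  prel: 0.25, w_mean: 0.37, w_median: 0.2}
    Ipv:  {pcon: 0.575, prel: 0.25, w_mean: 0.82, w_median: 0.68}
    I5ht: {pcon: 0.24,  prel: 0.25, w_mean: 0.39, w_median: 0.19}
    Isom: {pcon: 0.5,   prel: 0.25, w_mean: 0.5,  w_median: 0.4}
  Ipv:
    E:    {pcon: 0.6,   prel: 0.25, w_mean: 0.52, w_median: 0.29}
    Ipv:  {pcon: 0.55,  prel: 0.25, w_mean: 0.56, w_median: 0.44}
    I5ht: {pcon: 0.24,  prel: 0.25, w_mean: 0.83, w_median: 0.6}
    Isom: {pcon: 0.0}
  I5ht:
    E:    {pcon: 0.465, prel: 0.25, w_mean: 0.49, w_median: 0.3}
    Ipv:  {pcon: 0.38,  prel: 0.25, w_mean: 0.49, w_median: 0.15}
    I5ht: {pcon: 0.38,  prel: 0.25, w_mean: 0.37, w_median: 0.23}
    Isom: {pcon: 0.0}
  Isom:
    E:    {pcon: 0.5,   prel: 0.25, w_mean: 0.5,  w_median: 0.4}
    Ipv:  {pcon: 0.0}
    I5ht: {pcon: 0.0}
    Isom: {pcon: 0.0}
integration:
  dt_ms: 0.01
  trial_ms: 50.0
  l4_jitter_sd_ms: 2.0
  l4_center_ms: 25.0
psp_cap_mv: 8.0
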