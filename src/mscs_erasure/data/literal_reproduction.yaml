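# Literal-reproduction variant: midpoint fixed at the experimental
# 1.9 kBT/nm^2 and the printed energy gap of 22 kBT used in the heat rule
# (energy_mode: as_printed).  With these the kinetic and Boltzmann midpoints
# differ slightly, so the quasi-static mean heat does not converge exactly
# to ln2; see docs/methods.md.
params:
  delta_epsilon: 22.0
  delta_area: 12.0
  k_open_0: 4.0e-06
  k_close_0: 9897.0
  area_closed_to_barrier: 7.0
  area_open_to_barrier: -5.0
  energy_mode: as_printed
gamma_mid: 1.9
gamma_max: 3.0
load_s: 0.25
hold_s: 3.0
erase_durations: [0.25, 1.0, 5.0, 10.0]
n_realizations: 200
seed: 0
mode: exact_heat
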