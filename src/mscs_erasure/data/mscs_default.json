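{
  "delta_epsilon": 22.0,
  "delta_area": 12.0,
  "k_open_0": 4e-06,
  "k_close_0": 9897.0,
  "area_closed_to_barrier": 7.0,
  "area_open_to_barrier": -5.0,
  "energy_mode": "kinetic_consistent"
}
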