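# Default restore-to-open sweep: erasure ramp from the model's own midpoint
# tension to 3 kBT/nm^2, scored over the final ramp only (fast path,
# equilibrium 50/50 initialization at the ramp start).
gamma_max: 3.0
load_s: 0.25
hold_s: 3.0
erase_durations: [0.25, 1.0, 5.0, 10.0]
n_realizations: 200
seed: 0
mode: exact_heat
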