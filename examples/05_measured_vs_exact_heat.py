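"""Closure of the measurement arm: detected-event heat vs. simulator truth.

Runs the same erasure ensemble twice — scoring heat from the exact simulated
events, and from events re-detected in rendered low-noise traces — and shows
the two mean heats agree closely.
"""

from mscs_erasure import ExperimentConfig, RecordingConfig, run_erasure_experiment

base = dict(erase_durations=(1.0,), n_realizations=100, seed=5)
(exact,) = run_erasure_experiment(ExperimentConfig(**base))
(measured,) = run_erasure_experiment(
    ExperimentConfig(**base, mode="measured_heat",
                     recording=RecordingConfig(noise_sd=1.5))
)

print(f"exact-heat mean:    {exact.mean_heat_released:.4f} kBT "
      f"({exact.n_events} events)")
print(f"measured-heat mean: {measured.mean_heat_released:.4f} kBT "
      f"({measured.n_events} events)")
print(f"difference: {abs(exact.mean_heat_released - measured.mean_heat_released):.4f} kBT")
print("\nDetection localizes each step to ~1 sample, so the tension — and "
      "hence the heat — attached to each event is nearly exact at low noise.")
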