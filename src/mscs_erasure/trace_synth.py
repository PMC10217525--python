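"""Synthetic single/multi-channel patch-clamp current traces.

Renders simulated gating trajectories into the kind of recording an
inside-out excised patch produces at a 30 mV holding potential: each open
~1 nS channel adds a quantized ~30 pA step on top of a baseline, with
additive white Gaussian instrument noise and an optional single-pole
low-pass filter.  The true gating events ride along in the file header, so
event-detection benchmarks are self-contained.

The noise model is the standard idealization; 1/f and flicker noise,
capacitive transients and seal drift are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .simulator import OPENING, GatingEvent, Trajectory

__all__ = ["RecordingConfig", "CurrentTrace", "render_trace", "write_trace", "read_trace"]


@dataclass(frozen=True)
class RecordingConfig:
    """Instrument model for synthetic recordings.

    ``unitary_current`` defaults to 30 pA (1 nS channel at 30 mV);
    ``noise_sd`` and ``filter_cutoff`` are benchmarking choices, not
    measured values.
    """

    unitary_current: float = 30.0  # pA
    sampling_rate: float = 10_000.0  # Hz
    noise_sd: float = 3.0  # pA
    filter_cutoff: float | None = None  # Hz, single-pole low-pass
    baseline: float = 0.0  # pA
    baseline_drift: float = 0.0  # pA/s
    n_channels: int = 1

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.filter_cutoff is not None and self.sampling_rate <= 2 * self.filter_cutoff:
            raise ValueError("sampling_rate must exceed twice the filter cutoff")


@dataclass(frozen=True)
class CurrentTrace:
    """Uniformly sampled current recording, optionally with event truth."""

    time: np.ndarray  # s
    current: np.ndarray  # pA
    config: RecordingConfig | None = None
    truth: tuple[tuple[GatingEvent, ...], ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.time) != len(self.current):
            raise ValueError("time and current must have equal length")
        if len(self.time) > 2:
            dt = np.diff(self.time)
            if np.max(np.abs(dt - dt[0])) > 1e-12:
                raise ValueError("sampling must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


def _occupancy_on_grid(traj: Trajectory, grid: np.ndarray) -> np.ndarray:
    times = np.array([ev.time for ev in traj.events])
    states = np.empty(len(times) + 1)
    states[0] = traj.initial_state
    for k, ev in enumerate(traj.events):
        states[k + 1] = 1.0 if ev.direction == OPENING else 0.0
    if len(times) == 0:
        return np.full(len(grid), float(traj.initial_state))
    return states[np.searchsorted(times, grid, side="right")]


def render_trace(
    trajectories: Sequence[Trajectory],
    config: RecordingConfig,
    rng: np.random.Generator,
    duration: float | None = None,
) -> CurrentTrace:
    """Render trajectories (sharing one protocol) into a current trace.

    current(t) = baseline + drift*t + unitary * (#channels open at t)
    + N(0, noise_sd), then the optional low-pass applied to signal+noise.
    """
    if not trajectories:
        raise ValueError("empty trajectory list")
    total = duration if duration is not None else trajectories[0].protocol.total_duration
    n_samp = int(round(total * config.sampling_rate))
    grid = np.arange(n_samp) / config.sampling_rate
    level = np.zeros(n_samp)
    for tr in trajectories:
        level += _occupancy_on_grid(tr, grid)
    current = (
        config.baseline
        + config.baseline_drift * grid
        + config.unitary_current * level
    )
    if config.noise_sd > 0:
        current = current + rng.normal(0.0, config.noise_sd, n_samp)
    if config.filter_cutoff is not None:
        # single-pole RC low-pass, discretized (exponential smoothing)
        alpha = 1.0 - np.exp(-2.0 * np.pi * config.filter_cutoff / config.sampling_rate)
        current = lfilter([alpha], [1.0, alpha - 1.0], current, zi=[current[0] * (1 - alpha)])[0]
    cfg = RecordingConfig(**{**asdict(config), "n_channels": len(trajectories)})
    truth = tuple(tr.events for tr in trajectories)
    return CurrentTrace(grid, np.asarray(current), cfg, truth)


# -- file I/O ---------------------------------------------------------------
# Two-column CSV (time_s, current_pA); config and truth ride in '#'-prefixed
# JSON header lines so a trace file is a self-contained benchmark.


def write_trace(path: str | Path, trace: CurrentTrace) -> None:
    path = Path(path)
    lines = []
    if trace.config is not None:
        cfg = {k: v for k, v in asdict(trace.config).items()}
        lines.append("# config: " + json.dumps(cfg))
    if trace.truth is not None:
        truth = [
            [[ev.time, ev.direction, ev.tension_at_event] for ev in ch]
            for ch in trace.truth
        ]
        lines.append("# truth: " + json.dumps(truth))
    lines.append("time_s,current_pA")
    body = "\n".join(
        f"{t:.9f},{c:.6f}" for t, c in zip(trace.time, trace.current)
    )
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def read_trace(path: str | Path) -> CurrentTrace:
    path = Path(path)
    config = None
    truth = None
    header_rows = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("# config:"):
                config = RecordingConfig(**json.loads(line.split(":", 1)[1]))
                header_rows += 1
            elif line.startswith("# truth:"):
                raw = json.loads(line.split(":", 1)[1])
                truth = tuple(
                    tuple(GatingEvent(t, d, g) for t, d, g in ch) for ch in raw
                )
                header_rows += 1
            else:
                break
    arr = np.genfromtxt(path, delimiter=",", skip_header=header_rows, names=True)
    if arr.dtype.names is None or len(arr.dtype.names) < 2:
        raise ValueError(f"{path}: expected two columns (time_s, current_pA)")
    names = arr.dtype.names
    time = np.atleast_1d(arr[names[0]]).astype(float)
    current = np.atleast_1d(arr[names[1]]).astype(float)
    if np.isnan(time).any() or np.isnan(current).any():
        raise ValueError(f"{path}: malformed numeric data")
    return CurrentTrace(time, current, config, truth)
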