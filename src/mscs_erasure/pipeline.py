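"""Full erasure experiment: simulate each duration, score heat, emit tables.

For every erasure-ramp duration in the config this builds the
restore-to-open protocol, simulates an ensemble of independent channels,
optionally renders synthetic current traces and re-measures the events with
the edge detector, and accumulates the per-duration heat statistics into a
plot-ready table (duration vs. mean released heat with SEM, alongside the
Landauer bound).  Runs are deterministic given the seed; every run writes a
manifest with the resolved config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .channel_model import ChannelParams, default_params, midpoint_tension
from .protocol import TensionProtocol, make_erasure_ramp, make_restore_to_open
from .simulator import Trajectory, simulate_ensemble
from .thermo import EnsembleSummary, summarize_ensemble
from .trace_synth import RecordingConfig, render_trace

__all__ = ["ExperimentConfig", "run_erasure_experiment", "summaries_to_frame"]

log = logging.getLogger("mscs_erasure")


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one restore-to-open experiment sweep."""

    params: ChannelParams = field(default_factory=default_params)
    gamma_mid: float | None = None  # None -> the model's own midpoint
    gamma_max: float = 3.0
    load_s: float = 0.25
    hold_s: float = 3.0
    erase_durations: tuple[float, ...] = (0.25, 1.0, 5.0, 10.0)
    n_realizations: int = 200
    seed: int = 0
    mode: str = "exact_heat"  # or "measured_heat"
    full_protocol: bool = False  # simulate load+hold from closed vs. fast path
    recording: RecordingConfig = field(default_factory=RecordingConfig)
    kernel_halfwidth: int = 16
    threshold_sigmas: float = 6.0

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if len(set(self.erase_durations)) != len(self.erase_durations):
            raise ValueError("erase durations must be unique")
        if any(d <= 0 for d in self.erase_durations):
            raise ValueError("erase durations must be positive")
        if self.mode not in ("exact_heat", "measured_heat"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def gamma_mid_value(self) -> float:
        return self.gamma_mid if self.gamma_mid is not None else midpoint_tension(self.params)

    def protocol_for(self, erase_s: float) -> TensionProtocol:
        if self.full_protocol:
            return make_restore_to_open(
                self.gamma_mid_value, self.gamma_max, self.load_s, self.hold_s, erase_s
            )
        return make_erasure_ramp(self.gamma_mid_value, self.gamma_max, erase_s)

    # -- YAML round trip ---------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; expected a subset of {sorted(known)}"
            )
        kw = dict(raw)
        if "params" in kw and isinstance(kw["params"], dict):
            kw["params"] = ChannelParams.from_dict(kw["params"])
        if "recording" in kw and isinstance(kw["recording"], dict):
            kw["recording"] = RecordingConfig(**kw["recording"])
        if "erase_durations" in kw:
            kw["erase_durations"] = tuple(float(d) for d in kw["erase_durations"])
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["erase_durations"] = list(self.erase_durations)
        return d


def _run_one_duration(
    cfg: ExperimentConfig, erase_s: float, seed: np.random.SeedSequence
) -> tuple[EnsembleSummary, list[Trajectory]]:
    prot = cfg.protocol_for(erase_s)
    init = "fixed_closed" if cfg.full_protocol else "equilibrium_at_start"
    trajs = simulate_ensemble(cfg.params, prot, cfg.n_realizations, init, seed)
    if cfg.mode == "measured_heat":
        from .edge_detect import detect_steps, events_to_tension
        from .thermo import event_heat_released, _hist, landauer_bound

        rng = np.random.default_rng(seed.spawn(1)[0])
        window = prot.erasure_window
        # one patch per realization: render and re-measure each trajectory
        heats, ev_heats = [], []
        for tr in trajs:
            trace = render_trace([tr], cfg.recording, rng)
            table = detect_steps(trace, cfg.kernel_halfwidth, cfg.threshold_sigmas)
            q = [
                event_heat_released(cfg.params, ev)
                for ev in events_to_tension(table, prot)
                if window[0] <= ev.time <= window[1]
            ]
            heats.append(sum(q))
            ev_heats.extend(q)
        heats = np.asarray(heats, dtype=float)
        ev = np.asarray(ev_heats, dtype=float)
        n = len(heats)
        summary = EnsembleSummary(
            erase_duration=window[1] - window[0],
            n_realizations=n,
            mean_heat_released=float(heats.mean()),
            sem_heat_released=float(heats.std(ddof=1) / math.sqrt(n)) if n > 1 else None,
            mean_heat_per_event=float(ev.mean()) if len(ev) else None,
            sem_heat_per_event=(
                float(ev.std(ddof=1) / math.sqrt(len(ev))) if len(ev) > 1 else None
            ),
            n_events=len(ev),
            heat_histogram=_hist(heats, "fd"),
            event_heat_histogram=_hist(ev, "fd"),
            landauer_bound=landauer_bound(
                cfg.params,
                prot.tension_at(window[0]),
                prot.tension_at(window[1]),
            ),
        )
        return summary, trajs
    return summarize_ensemble(cfg.params, trajs), trajs


def run_erasure_experiment(
    cfg: ExperimentConfig, out_dir: str | Path | None = None
) -> list[EnsembleSummary]:
    """Run the duration sweep; optionally write TSV/JSON artifacts.

    Writes ``summary.tsv`` (one row per duration), per-duration histogram
    TSVs and ``manifest.json`` (resolved config + seed) when ``out_dir`` is
    given.  Deterministic for a fixed config.
    """
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(len(cfg.erase_durations))
    summaries = []
    for erase_s, child in zip(cfg.erase_durations, children):
        summary, _ = _run_one_duration(cfg, erase_s, child)
        log.info(
            "duration %6.2f s: mean heat %.4f kBT (n=%d, %d events), bound %.4f",
            erase_s, summary.mean_heat_released, summary.n_realizations,
            summary.n_events, summary.landauer_bound,
        )
        summaries.append(summary)
    if out_dir is not None:
        _write_outputs(cfg, summaries, Path(out_dir))
    return summaries


def summaries_to_frame(summaries: Sequence[EnsembleSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "erase_duration_s": s.erase_duration,
                "n_realizations": s.n_realizations,
                "mean_heat_kBT": s.mean_heat_released,
                "sem_heat_kBT": s.sem_heat_released,
                "mean_heat_per_event_kBT": s.mean_heat_per_event,
                "sem_heat_per_event_kBT": s.sem_heat_per_event,
                "n_events": s.n_events,
                "landauer_bound_kBT": s.landauer_bound,
            }
            for s in summaries
        ]
    )


def _write_outputs(
    cfg: ExperimentConfig, summaries: Sequence[EnsembleSummary], out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    summaries_to_frame(summaries).to_csv(out / "summary.tsv", sep="\t", index=False)
    for s in summaries:
        for tag, (edges, counts) in (
            ("realizations", s.heat_histogram),
            ("events", s.event_heat_histogram),
        ):
            df = pd.DataFrame(
                {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
            )
            df.to_csv(
                out / f"hist_{tag}_tau{s.erase_duration:g}s.tsv", sep="\t", index=False
            )
    manifest = {"config": cfg.to_dict(), "n_durations": len(summaries)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
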