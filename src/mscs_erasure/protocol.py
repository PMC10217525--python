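"""Piecewise-linear tension protocols and pipette-pressure calibration.

The gating stimulus is membrane tension gamma(t) in kBT/nm^2, represented as
an ordered list of linear segments.  The canonical "restore-to-open" stimulus
ramps from zero to the midpoint tension, holds there so the channel
thermalises into a 50/50 (one-bit) mixture, then ramps to a saturating
tension where the open state is certain — a Landauer-style erasure.  Heat and
work are scored over the final (erasure) ramp.

Pipette pressure enters only at the calibration boundary: recordings control
suction pressure p, and tension is obtained by proportional calibration
against the activation midpoint, gamma = (p / p_half) * gamma_half, with
gamma_half in mN/m converted at 4.114 mN/m per kBT/nm^2.
"""

from __future__ import annotations

import bisect
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Segment",
    "TensionProtocol",
    "CalibrationParams",
    "MN_PER_M_PER_KBT_NM2",
    "tension_at",
    "make_restore_to_open",
    "make_erasure_ramp",
    "make_hold",
    "fit_segments",
    "pressure_to_tension",
]

#: mN/m equivalent of 1 kBT/nm^2 at room temperature.
MN_PER_M_PER_KBT_NM2 = 4.114


@dataclass(frozen=True)
class Segment:
    """One linear piece of a tension protocol."""

    duration: float  # s
    start_tension: float  # kBT/nm^2
    end_tension: float  # kBT/nm^2

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.start_tension < 0 or self.end_tension < 0:
            raise ValueError("tensions must be non-negative")

    @property
    def slope(self) -> float:
        return (self.end_tension - self.start_tension) / self.duration


@dataclass(frozen=True)
class TensionProtocol:
    """Ordered piecewise-linear tension-vs-time stimulus.

    ``erasure_window`` marks the (t_start, t_end) interval over which heat
    and work are scored; by default the whole protocol.
    """

    segments: tuple[Segment, ...]
    erasure_window: tuple[float, float] | None = None
    _starts: tuple[float, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for a, b in zip(self.segments, self.segments[1:]):
            if not math.isclose(a.end_tension, b.start_tension,
                                rel_tol=1e-12, abs_tol=1e-12):
                raise ValueError("tension must be continuous across segments")
        starts = [0.0]
        for seg in self.segments:
            starts.append(starts[-1] + seg.duration)
        object.__setattr__(self, "_starts", tuple(starts))
        if self.erasure_window is None:
            object.__setattr__(self, "erasure_window", (0.0, self.total_duration))
        t0, t1 = self.erasure_window
        if not (0.0 <= t0 < t1 <= self.total_duration + 1e-12):
            raise ValueError("erasure_window must lie within the protocol")

    @property
    def total_duration(self) -> float:
        return self._starts[-1]

    @property
    def breakpoints(self) -> tuple[float, ...]:
        """Segment boundary times, including 0 and total_duration."""
        return self._starts

    def segment_index(self, t: float) -> int:
        """Index of the segment containing time ``t`` (right-open intervals)."""
        if t < 0 or t > self.total_duration + 1e-12:
            raise ValueError(f"time {t} outside protocol [0, {self.total_duration}]")
        i = bisect.bisect_right(self._starts, t) - 1
        return min(i, len(self.segments) - 1)

    def tension_at(self, t: float) -> float:
        i = self.segment_index(t)
        seg = self.segments[i]
        return seg.start_tension + seg.slope * (t - self._starts[i])

    # -- serialization / export --------------------------------------

    def to_dict(self) -> dict:
        return {
            "segments": [
                [s.duration, s.start_tension, s.end_tension] for s in self.segments
            ],
            "erasure_window": list(self.erasure_window),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TensionProtocol":
        segs = tuple(Segment(*row) for row in d["segments"])
        window = tuple(d["erasure_window"]) if d.get("erasure_window") else None
        return cls(segs, window)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TensionProtocol":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_table(self, n_per_segment: int = 50) -> np.ndarray:
        """Dense (t, gamma) table on a per-segment grid, breakpoints included."""
        ts: list[float] = []
        for i, seg in enumerate(self.segments):
            t0 = self._starts[i]
            ts.extend(t0 + seg.duration * k / n_per_segment for k in range(n_per_segment))
        ts.append(self.total_duration)
        t = np.asarray(ts)
        g = np.asarray([self.tension_at(x) for x in ts])
        return np.column_stack([t, g])

    def to_tsv(self, path: str | Path, n_per_segment: int = 50) -> None:
        tab = self.to_table(n_per_segment)
        header = "time_s\ttension_kBT_per_nm2"
        np.savetxt(path, tab, delimiter="\t", header=header, comments="")


def fit_segments(table: np.ndarray, atol: float = 1e-9) -> TensionProtocol:
    """Recover a piecewise-linear protocol from a dense (t, gamma) table.

    Breakpoints are placed where the local slope changes by more than
    ``atol``; on tables produced by :meth:`TensionProtocol.to_table` this
    recovers the original segment boundaries exactly.
    """
    t = np.asarray(table)[:, 0]
    g = np.asarray(table)[:, 1]
    if len(t) < 2:
        raise ValueError("need at least two samples")
    slopes = np.diff(g) / np.diff(t)
    cuts = [0]
    for i in range(1, len(slopes)):
        if abs(slopes[i] - slopes[i - 1]) > atol:
            cuts.append(i)
    cuts.append(len(t) - 1)
    segs = tuple(
        Segment(t[b] - t[a], g[a], g[b]) for a, b in zip(cuts, cuts[1:])
    )
    return TensionProtocol(segs)


@dataclass(frozen=True)
class CalibrationParams:
    """Proportional pressure->tension calibration.

    ``p_half`` is the pressure (mmHg) at the channel activation midpoint,
    ``gamma_half`` the midpoint tension in mN/m (7.85 mN/m for MscS).
    """

    p_half: float
    gamma_half: float = 7.85
    conversion: float = MN_PER_M_PER_KBT_NM2

    def __post_init__(self) -> None:
        if self.p_half <= 0:
            raise ValueError("p_half must be positive")
        if self.gamma_half <= 0:
            raise ValueError("gamma_half must be positive")


def tension_at(protocol: TensionProtocol, t: float) -> float:
    """Tension (kBT/nm^2) at protocol time ``t`` by linear interpolation."""
    return protocol.tension_at(t)


def make_restore_to_open(
    gamma_mid: float,
    gamma_max: float = 3.0,
    load_s: float = 0.25,
    hold_s: float = 3.0,
    erase_s: float = 1.0,
) -> TensionProtocol:
    """Build the restore-to-open stimulus: load ramp, hold, erasure ramp.

    Ramps 0 -> gamma_mid over ``load_s``, holds at gamma_mid for ``hold_s``
    (thermalisation into the maximal-uncertainty bit), then ramps
    gamma_mid -> gamma_max over ``erase_s``.  The erasure window is the
    final ramp.
    """
    if not gamma_max > gamma_mid >= 0:
        raise ValueError("need gamma_max > gamma_mid >= 0")
    segs = (
        Segment(load_s, 0.0, gamma_mid),
        Segment(hold_s, gamma_mid, gamma_mid),
        Segment(erase_s, gamma_mid, gamma_max),
    )
    t_start = load_s + hold_s
    return TensionProtocol(segs, erasure_window=(t_start, t_start + erase_s))


def make_erasure_ramp(gamma_mid: float, gamma_max: float = 3.0,
                      erase_s: float = 1.0) -> TensionProtocol:
    """Just the scored erasure ramp gamma_mid -> gamma_max (fast path)."""
    if not gamma_max > gamma_mid >= 0:
        raise ValueError("need gamma_max > gamma_mid >= 0")
    return TensionProtocol((Segment(erase_s, gamma_mid, gamma_max),))


def make_hold(gamma: float, duration: float) -> TensionProtocol:
    """Constant-tension protocol (useful for equilibrium checks)."""
    return TensionProtocol((Segment(duration, gamma, gamma),))


def pressure_to_tension(p: float, cal: CalibrationParams) -> float:
    """Convert pipette pressure (mmHg) to membrane tension (kBT/nm^2).

    gamma = (p / p_half) * gamma_half, with gamma_half expressed in mN/m and
    divided by 4.114 mN/m per kBT/nm^2.
    """
    if p < 0:
        raise ValueError("pressure must be non-negative")
    return (p / cal.p_half) * (cal.gamma_half / cal.conversion)
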