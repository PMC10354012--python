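"""Voltage-clamp pulse protocols and solution-application schedules.

A :class:`ProtocolSchedule` couples a list of per-sweep voltage segment
programs with an ordered list of solution blocks (bath K+ concentration and
compound concentration per contiguous sweep range).  Four canonical TEVC
protocols are provided:

``screening``
    Repetitive sweep (2 s at 0 mV, 0.5 s at -100 mV, 2 s at 0 mV; 4.5 s
    period) repeated 100 times (450 s total) with blocks low-K control /
    high-K control / high-K + compound / high-K washout / low-K washout.
``dose_response``
    Same sweep, 195 repetitions: low-K and high-K controls, six 25-sweep
    compound-concentration blocks, low-K washout.
``iv``
    40 s wash-in at -80 mV followed by 17 voltage steps from -120 to +40 mV
    in 10 mV increments, once without and once with compound.
``inactivation``
    Per sweep, a depolarizing +100 mV inter-pulse of variable duration
    followed by a 500 ms test pulse to -100 mV, run once in control and once
    in compound solution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

__all__ = ["Segment", "SolutionBlock", "ProtocolSchedule", "build_protocol_schedule"]


@dataclass(frozen=True)
class Segment:
    duration_ms: float
    voltage_mV: float

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("segment duration must be positive")


@dataclass(frozen=True)
class SolutionBlock:
    label: str
    first_sweep: int  # 1-based, inclusive
    last_sweep: int
    k_out_mM: float = 80.0
    compound_uM: float = 0.0
    ion: str = "K"

    def __post_init__(self) -> None:
        if self.first_sweep < 1 or self.last_sweep < self.first_sweep:
            raise ValueError(f"invalid sweep range in block {self.label!r}")
        if self.k_out_mM <= 0 or self.compound_uM < 0:
            raise ValueError(f"invalid solution in block {self.label!r}")


@dataclass(frozen=True)
class ProtocolSchedule:
    kind: str
    sweeps: tuple[tuple[Segment, ...], ...]
    blocks: tuple[SolutionBlock, ...]

    def __post_init__(self) -> None:
        n = self.n_sweeps
        covered = []
        for b in self.blocks:
            if b.last_sweep > n:
                raise ValueError(f"block {b.label!r} exceeds sweep count {n}")
            covered.extend(range(b.first_sweep, b.last_sweep + 1))
        if sorted(covered) != list(range(1, n + 1)):
            raise ValueError("solution blocks must tile 1..n_sweeps without gaps or overlap")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    def sweep_period_s(self, index: int = 0) -> float:
        return sum(seg.duration_ms for seg in self.sweeps[index]) / 1000.0

    @property
    def total_duration_s(self) -> float:
        return sum(self.sweep_period_s(i) for i in range(self.n_sweeps))

    def block_of(self, sweep_index: int) -> SolutionBlock:
        """Solution block containing a 1-based sweep index."""
        for b in self.blocks:
            if b.first_sweep <= sweep_index <= b.last_sweep:
                return b
        raise KeyError(f"sweep {sweep_index} outside schedule")

    def sweep_start_s(self, sweep_index: int) -> float:
        return sum(self.sweep_period_s(i) for i in range(sweep_index - 1))

    def segment_bounds_ms(self, sweep_index: int, segment_index: int) -> tuple[float, float]:
        segs = self.sweeps[sweep_index - 1]
        start = sum(s.duration_ms for s in segs[:segment_index])
        return start, start + segs[segment_index].duration_ms

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kind": self.kind,
            "sweeps": [
                [asdict(seg) for seg in sweep] for sweep in self.sweeps
            ],
            "blocks": [asdict(b) for b in self.blocks],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ProtocolSchedule":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            kind=payload["kind"],
            sweeps=tuple(
                tuple(Segment(**seg) for seg in sweep) for sweep in payload["sweeps"]
            ),
            blocks=tuple(SolutionBlock(**b) for b in payload["blocks"]),
        )


_SCREEN_SWEEP = (Segment(2000, 0.0), Segment(500, -100.0), Segment(2000, 0.0))

DEFAULT_DOSE_CONCENTRATIONS = (0.1, 1.0, 10.0, 30.0, 100.0, 300.0)
DEFAULT_INACTIVATION_DURATIONS = (10.0, 20.0, 30.0, 50.0, 75.0, 100.0, 150.0, 200.0)


def _screening(compound_uM: float, k_high_mM: float) -> ProtocolSchedule:
    sweeps = tuple(_SCREEN_SWEEP for _ in range(100))
    blocks = (
        SolutionBlock("low_K_control", 1, 15, k_out_mM=2.0),
        SolutionBlock("high_K_control", 16, 35, k_out_mM=k_high_mM),
        SolutionBlock("compound", 36, 65, k_out_mM=k_high_mM, compound_uM=compound_uM),
        SolutionBlock("high_K_washout", 66, 85, k_out_mM=k_high_mM),
        SolutionBlock("low_K_washout", 86, 100, k_out_mM=2.0),
    )
    return ProtocolSchedule(kind="screening", sweeps=sweeps, blocks=blocks)


def _dose_response(
    concentrations: Sequence[float], k_high_mM: float
) -> ProtocolSchedule:
    concentrations = tuple(concentrations)
    if len(concentrations) != 6:
        raise ValueError("dose-response schedule uses six concentration blocks")
    sweeps = tuple(_SCREEN_SWEEP for _ in range(195))
    blocks = [
        SolutionBlock("low_K_control", 1, 15, k_out_mM=2.0),
        SolutionBlock("high_K_control", 16, 30, k_out_mM=k_high_mM),
    ]
    first = 31
    for c in concentrations:
        blocks.append(
            SolutionBlock(
                f"compound_{c:g}uM", first, first + 24, k_out_mM=k_high_mM, compound_uM=c
            )
        )
        first += 25
    blocks.append(SolutionBlock("washout", 181, 195, k_out_mM=2.0))
    return ProtocolSchedule(kind="dose_response", sweeps=sweeps, blocks=tuple(blocks))


def _iv(compound_uM: float, k_high_mM: float, ion: str) -> ProtocolSchedule:
    washin = tuple(tuple([Segment(5000, -80.0)]) for _ in range(8))  # 40 s
    steps = tuple(
        tuple([Segment(500, v)]) for v in range(-120, 41, 10)
    )  # 17 steps
    sweeps = washin + steps + washin + steps
    blocks = (
        SolutionBlock("washin_control", 1, 8, k_out_mM=k_high_mM, ion=ion),
        SolutionBlock("iv_control", 9, 25, k_out_mM=k_high_mM, ion=ion),
        SolutionBlock(
            "washin_compound", 26, 33, k_out_mM=k_high_mM, compound_uM=compound_uM, ion=ion
        ),
        SolutionBlock(
            "iv_compound", 34, 50, k_out_mM=k_high_mM, compound_uM=compound_uM, ion=ion
        ),
    )
    return ProtocolSchedule(kind="iv", sweeps=sweeps, blocks=blocks)


def _inactivation(
    durations_ms: Sequence[float], compound_uM: float, k_high_mM: float
) -> ProtocolSchedule:
    def sweep(x: float) -> tuple[Segment, ...]:
        return (
            Segment(100, -80.0),
            Segment(x, 100.0),
            Segment(500, -100.0),
            Segment(100, -80.0),
        )

    durations_ms = tuple(durations_ms)
    # 50 s compound wash-in at -80 mV between the two protocol applications
    washin = tuple(tuple([Segment(5000, -80.0)]) for _ in range(10))
    sweeps = tuple(sweep(x) for x in durations_ms) + washin + tuple(
        sweep(x) for x in durations_ms
    )
    n = len(durations_ms)
    blocks = (
        SolutionBlock("control", 1, n, k_out_mM=k_high_mM),
        SolutionBlock(
            "washin", n + 1, n + 10, k_out_mM=k_high_mM, compound_uM=compound_uM
        ),
        SolutionBlock(
            "compound", n + 11, 2 * n + 10, k_out_mM=k_high_mM, compound_uM=compound_uM
        ),
    )
    return ProtocolSchedule(kind="inactivation", sweeps=sweeps, blocks=blocks)


def build_protocol_schedule(kind: str, **params) -> ProtocolSchedule:
    """Build one of the canonical TEVC schedules; see the module docstring."""

    def done(schedule: ProtocolSchedule) -> ProtocolSchedule:
        if params:
            raise ValueError(f"unknown parameters for kind {kind!r}: {sorted(params)}")
        return schedule

    if kind == "screening":
        return done(
            _screening(
                compound_uM=params.pop("compound_uM", 100.0),
                k_high_mM=params.pop("k_high_mM", 80.0),
            )
        )
    if kind == "dose_response":
        return done(
            _dose_response(
                concentrations=params.pop("concentrations", DEFAULT_DOSE_CONCENTRATIONS),
                k_high_mM=params.pop("k_high_mM", 80.0),
            )
        )
    if kind == "iv":
        return done(
            _iv(
                compound_uM=params.pop("compound_uM", 100.0),
                k_high_mM=params.pop("k_high_mM", 80.0),
                ion=params.pop("ion", "K"),
            )
        )
    if kind == "inactivation":
        return done(
            _inactivation(
                durations_ms=params.pop("durations_ms", DEFAULT_INACTIVATION_DURATIONS),
                compound_uM=params.pop("compound_uM", 100.0),
                k_high_mM=params.pop("k_high_mM", 100.0),
            )
        )
    raise ValueError(f"unknown protocol kind {kind!r}")
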