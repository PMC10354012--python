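"""Stochastic single-file ion-hopping surrogate of selectivity-filter permeation.

A continuous-time Markov jump process over the binding-site ladder
``intracellular bulk <-> cavity <-> S4 <-> S3 <-> S2 <-> S1 <-> extracellular``
with hard single-file exclusion (at most one ion per site).  Four labelled
ions start stacked in the filter (role 1 at S1 ... role 4 at S4); an
unlimited reservoir feeds the cavity, and ions leaving either end are parked
in the corresponding bulk pool from which they may re-enter last-in
first-out.  Outward (intracellular-to-extracellular) rates can be biased by
a multiplicative factor emulating a transmembrane electrostatic field.

The process is a statistical surrogate: its rates are free parameters with
no claim of physical fidelity.  Emitted observables are distances of the
labelled ions to the S1 reference residue on a uniform sampling grid, with
Gaussian jitter and a short linear transit ramp after each hop so that
between-site presence in occupancy histograms reflects hopping traffic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..permeation import DEFAULT_SITE_MAP, IonDistanceSeries, series_to_frame

__all__ = [
    "PermeationModelConfig",
    "PermeationRun",
    "ReplicateStats",
    "simulate_sf_permeation",
    "wt_config",
    "t322a_config",
]

# ladder edges in outward (conduction) direction; "bulk" is the
# intracellular reservoir, "out" the extracellular side
LADDER: tuple[str, ...] = ("bulk", "cavity", "S4", "S3", "S2", "S1", "out")
EDGES: tuple[tuple[str, str], ...] = tuple(zip(LADDER[:-1], LADDER[1:]))

#: forward (outward) / backward rate in 1/ns per ladder edge
DEFAULT_HOP_RATES: dict[tuple[str, str], tuple[float, float]] = {
    ("bulk", "cavity"): (0.40, 0.40),
    ("cavity", "S4"): (0.60, 0.60),
    ("S4", "S3"): (1.20, 1.20),
    ("S3", "S2"): (1.00, 1.00),
    ("S2", "S1"): (1.00, 1.00),
    ("S1", "out"): (0.04, 0.04),
}


@dataclass(frozen=True)
class PermeationModelConfig:
    """Parameters of the single-file hopping surrogate.

    ``site_distance_map`` gives the canonical distance (A) of each in-filter
    site to the S1 reference; exited ions are parked at ``out_distance_A``
    (just past the cavity end of the 0-16 A histogram axis, and beyond the
    5 A leave criterion used by the exclusion rule) and ions in the
    intracellular reservoir at ``bulk_distance_A`` (off-axis).  Replicate
    ``r`` runs with the deterministic child seed ``seed + r``.
    """

    site_distance_map: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_MAP)
    )
    hop_rates: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HOP_RATES)
    )
    voltage_bias: float = 1.0
    entry_rate: float | None = None  # overrides (bulk, cavity) forward rate
    out_distance_A: float = 16.5
    bulk_distance_A: float = 18.0
    transit_time_ns: float = 0.2
    jitter_sd: float = 0.4
    duration_ns: float = 150.0
    sample_interval_ns: float = 0.1
    n_replicates: int = 3
    species: str = "K"
    variant: str = "WT"
    initial_sites: tuple[str, ...] = ("S1", "S2", "S3", "S4")
    seed: int = 0

    def __post_init__(self) -> None:
        sm = dict(self.site_distance_map)
        order = ["S1", "S2", "S3", "S4", "cavity"]
        if sorted(sm) != sorted(order):
            raise ValueError(f"site_distance_map must define exactly {order}")
        pos = [sm[s] for s in order]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("site distances must increase strictly from S1 outward")
        rates = dict(self.hop_rates)
        for edge in EDGES:
            if edge not in rates:
                raise ValueError(f"missing hop rate for edge {edge}")
            f, b = rates[edge]
            if f < 0 or b < 0:
                raise ValueError(f"negative rate on edge {edge}")
        if self.voltage_bias < 0 or self.jitter_sd < 0 or self.transit_time_ns < 0:
            raise ValueError("voltage_bias, jitter_sd and transit_time_ns must be >= 0")
        if self.entry_rate is not None and self.entry_rate < 0:
            raise ValueError("entry_rate must be >= 0")
        n = self.duration_ns / self.sample_interval_ns
        if self.sample_interval_ns <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("sample_interval must divide duration")
        if not set(self.initial_sites) <= {"S1", "S2", "S3", "S4", "cavity"}:
            raise ValueError("initial_sites must be in-filter sites")
        if len(set(self.initial_sites)) != len(self.initial_sites):
            raise ValueError("initial_sites must be distinct (single-file)")
        object.__setattr__(self, "site_distance_map", sm)
        object.__setattr__(self, "hop_rates", rates)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ns / self.sample_interval_ns))

    def effective_rates(self) -> dict[tuple[str, str], tuple[float, float]]:
        rates = {k: list(v) for k, v in self.hop_rates.items()}
        if self.entry_rate is not None:
            rates[("bulk", "cavity")][0] = self.entry_rate
        return {k: (v[0] * self.voltage_bias, v[1]) for k, v in rates.items()}

    def ion_prefix(self) -> str:
        return "Rb" if self.species.lower().startswith("rb") else "K"


def wt_config(**overrides) -> PermeationModelConfig:
    """Wild-type K+ defaults."""
    return PermeationModelConfig(**overrides)


def t322a_config(inner_scale: float = 0.25, **overrides) -> PermeationModelConfig:
    """Inner-filter-slowed variant emulating the T322A phenotype.

    The S3<->S2 and S2<->S1 hop rates are scaled by ``inner_scale`` (< 1),
    which slows the 3rd/4th permeation steps and thins between-site hopping
    traffic.  The scale is a free emulation parameter, not a measured value.
    """
    rates = {k: tuple(v) for k, v in DEFAULT_HOP_RATES.items()}
    for edge in (("S3", "S2"), ("S2", "S1")):
        f, b = rates[edge]
        rates[edge] = (f * inner_scale, b * inner_scale)
    overrides.setdefault("hop_rates", rates)
    overrides.setdefault("variant", "T322A")
    return PermeationModelConfig(**overrides)


def esf_config(
    variant: str = "WT", inner_scale: float = 0.25, **overrides
) -> PermeationModelConfig:
    """Field-driven conduction run for first-passage transition timing.

    Emulates a simulation under an outward electrostatic field: outward rates
    are biased and the extracellular exit step is fast, so the inner-filter
    hops are rate-limiting and variant differences show up in the 3rd/4th
    transition times.  Runs default to 100 ns, the duration used for the
    conduction (as opposed to occupancy) protocol.
    """
    base = DEFAULT_HOP_RATES if variant == "WT" else dict(
        t322a_config(inner_scale).hop_rates
    )
    rates = {k: tuple(v) for k, v in base.items()}
    rates[("S1", "out")] = (0.5, 0.1)
    overrides.setdefault("hop_rates", rates)
    overrides.setdefault("voltage_bias", 2.5)
    overrides.setdefault("duration_ns", 100.0)
    overrides.setdefault("variant", variant)
    return PermeationModelConfig(**overrides)


def rb_config(variant: str = "WT", **overrides) -> PermeationModelConfig:
    """Rb+ emulation: fast loss of the outermost ion plus altered inner rates."""
    base = DEFAULT_HOP_RATES if variant == "WT" else t322a_config().hop_rates
    rates = {k: tuple(v) for k, v in base.items()}
    rates[("S1", "out")] = (0.8, 0.02)
    f, b = rates[("S3", "S2")]
    rates[("S3", "S2")] = (f * 0.6, b * 0.9)
    overrides.setdefault("hop_rates", rates)
    overrides.setdefault("species", "Rb")
    overrides.setdefault("variant", variant)
    return PermeationModelConfig(**overrides)


@dataclass(frozen=True)
class ReplicateStats:
    replicate_id: int
    n_jumps: int
    n_outward_exits: int
    n_inward_returns: int
    absorbed: bool  # total rate hit zero with ions still in the filter


@dataclass(frozen=True)
class PermeationRun:
    config: PermeationModelConfig
    series: tuple[IonDistanceSeries, ...]
    stats: tuple[ReplicateStats, ...]

    @property
    def net_outward(self) -> int:
        return sum(s.n_outward_exits - s.n_inward_returns for s in self.stats)

    def to_frame(self) -> pd.DataFrame:
        return series_to_frame(self.series)

    def write_csv(self, path: str | Path) -> None:
        path = Path(path)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        self.to_frame().to_csv(path, sep=sep, index=False)


def _simulate_replicate(
    config: PermeationModelConfig, replicate_id: int
) -> tuple[list[IonDistanceSeries], ReplicateStats]:
    rng = np.random.default_rng(config.seed + replicate_id)
    rates = config.effective_rates()
    prefix = config.ion_prefix()

    occupant: dict[str, str | None] = {
        s: None for s in ("cavity", "S4", "S3", "S2", "S1")
    }
    tracked = [f"{prefix}{i + 1}" for i in range(len(config.initial_sites))]
    for ion, site in zip(tracked, config.initial_sites):
        occupant[site] = ion
    out_pool: list[str] = []  # LIFO, extracellular side
    bulk_pool: list[str] = []  # LIFO, tracked ions only; reservoir is infinite
    spawn_counter = 0

    # itinerary per tracked ion: (hop time, new station); stations are ladder
    # labels plus the two pools
    site_of: dict[str, str] = {ion: site for ion, site in zip(tracked, config.initial_sites)}
    itinerary: dict[str, list[tuple[float, str]]] = {
        ion: [(0.0, site_of[ion])] for ion in tracked
    }

    t = 0.0
    n_jumps = n_out = n_in = 0
    absorbed = False
    T = config.duration_ns

    def possible_moves():
        moves = []  # (rate, src, dst)
        for (a, b), (fw, bw) in rates.items():
            # outward a -> b
            if fw > 0:
                if a == "bulk":
                    if occupant["cavity"] is None:
                        moves.append((fw, "bulk", "cavity"))
                elif b == "out":
                    if occupant[a] is not None:
                        moves.append((fw, a, "out"))
                elif occupant[a] is not None and occupant[b] is None:
                    moves.append((fw, a, b))
            # backward b -> a
            if bw > 0:
                if b == "out":
                    if out_pool and occupant[a] is None:
                        moves.append((bw, "out", a))
                elif a == "bulk":
                    if occupant[b] is not None:
                        moves.append((bw, b, "bulk"))
                elif occupant[b] is not None and occupant[a] is None:
                    moves.append((bw, b, a))
        return moves

    while True:
        moves = possible_moves()
        total = sum(m[0] for m in moves)
        if total <= 0.0:
            if any(occupant[s] is not None for s in occupant):
                absorbed = True
            break
        t += rng.exponential(1.0 / total)
        if t >= T:
            break
        u = rng.random() * total
        acc = 0.0
        for rate, src, dst in moves:
            acc += rate
            if u <= acc:
                break
        n_jumps += 1
        if src == "bulk":
            ion = bulk_pool.pop() if bulk_pool else None
            if ion is None:
                spawn_counter += 1
                ion = f"_u{spawn_counter}"
            occupant["cavity"] = ion
        elif src == "out":
            ion = out_pool.pop()
            occupant[dst] = ion
            n_in += 1
        else:
            ion = occupant[src]
            occupant[src] = None
            if dst == "out":
                out_pool.append(ion)
                n_out += 1
            elif dst == "bulk":
                if not ion.startswith("_u"):
                    bulk_pool.append(ion)
            else:
                occupant[dst] = ion
        if not ion.startswith("_u"):
            station = dst if dst in ("out", "bulk") else dst
            itinerary[ion].append((t, station))

    # emit sampled distance series
    dist_of = dict(config.site_distance_map)
    dist_of["out"] = config.out_distance_A
    dist_of["bulk"] = config.bulk_distance_A
    grid = np.arange(1, config.n_samples + 1) * config.sample_interval_ns
    series = []
    for ion in tracked:
        events = itinerary[ion]
        ev_t = np.array([e[0] for e in events])
        ev_d = np.array([dist_of[e[1]] for e in events])
        # pool hops (exit/entry) are teleports on the distance axis; only
        # in-filter hops get the linear transit ramp
        in_filter = np.array(
            [e[1] not in ("out", "bulk") for e in events], dtype=bool
        )
        idx = np.searchsorted(ev_t, grid, side="right") - 1
        d = ev_d[idx]
        if config.transit_time_ns > 0:
            since = grid - ev_t[idx]
            ramp = (
                (idx > 0)
                & (since < config.transit_time_ns)
                & in_filter[idx]
                & in_filter[np.maximum(idx - 1, 0)]
            )
            if ramp.any():
                frac = since[ramp] / config.transit_time_ns
                d = d.copy()
                d[ramp] = ev_d[idx[ramp] - 1] + frac * (
                    ev_d[idx[ramp]] - ev_d[idx[ramp] - 1]
                )
        if config.jitter_sd > 0:
            d = d + rng.normal(0.0, config.jitter_sd, size=d.size)
        d = np.clip(d, 0.0, None)
        series.append(
            IonDistanceSeries(
                replicate_id=replicate_id,
                ion_id=ion,
                species=config.species,
                times=grid,
                distances=d,
            )
        )
    stats = ReplicateStats(
        replicate_id=replicate_id,
        n_jumps=n_jumps,
        n_outward_exits=n_out,
        n_inward_returns=n_in,
        absorbed=absorbed,
    )
    return series, stats


def simulate_sf_permeation(config: PermeationModelConfig) -> PermeationRun:
    """Run the hopping surrogate for every replicate of a condition.

    Replicate seeds derive deterministically from the master seed
    (``seed + replicate``), so growing ``n_replicates`` never reshuffles
    earlier replicates.  A replicate whose total event rate reaches zero with
    ions still inside the filter is reported through
    ``ReplicateStats.absorbed`` (its series are still emitted: frozen chains
    are legitimate, e.g. for pinned-ion calibration runs).
    """
    all_series: list[IonDistanceSeries] = []
    all_stats: list[ReplicateStats] = []
    for r in range(config.n_replicates):
        series, stats = _simulate_replicate(config, r)
        all_series.extend(series)
        all_stats.append(stats)
    return PermeationRun(
        config=config, series=tuple(all_series), stats=tuple(all_stats)
    )
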