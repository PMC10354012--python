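"""Post-analysis of ion-to-reference distance trajectories from a selectivity filter.

The raw material is, per simulation replicate, the distance of each of the
four filter ions (roles ``K1``..``K4`` or ``Rb1``..``Rb4``, numbered from the
outermost S1 site inward) to the residue forming the outer S1 binding site,
sampled on a uniform time grid.  From these series the module derives

* a boundary-ion exclusion filter that removes records of ions that have
  left the filter,
* relative site-occupancy histograms along the filter axis and their
  wild-type-versus-mutant difference,
* hysteresis-debounced site assignments, and
* first-passage times of the innermost (tracked) ion through the four
  permeation steps S4 -> S3 -> S2 -> S1 -> out of the filter, with
  censoring for steps not reached within the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SITE_MAP",
    "IonDistanceSeries",
    "OccupancyHistogram",
    "DeltaHistogram",
    "ExclusionReport",
    "TransitionTable",
    "PermeationSummary",
    "read_ion_distance_table",
    "series_to_frame",
    "apply_sf_exclusion",
    "compute_occupancy_histogram",
    "read_occupancy_tsv",
    "compare_occupancy",
    "assign_sites",
    "detect_transitions",
    "summarize_permeation",
]

#: Canonical distance (Angstrom) of each ladder site to the S1-forming
#: reference residue, innermost (cavity) farthest away.  The filter axis is
#: binned over 0-16 A downstream, so the sites spread across that range.
DEFAULT_SITE_MAP: dict[str, float] = {
    "S1": 1.5,
    "S2": 4.5,
    "S3": 7.5,
    "S4": 10.5,
    "cavity": 14.0,
}

#: Permeation (conduction) order of stations, intracellular to extracellular.
PERMEATION_ORDER: tuple[str, ...] = ("cavity", "S4", "S3", "S2", "S1", "out")

REQUIRED_COLUMNS = ("replicate", "time_ns", "ion_id", "species", "distance_A")


@dataclass(frozen=True)
class IonDistanceSeries:
    """Distance of one ion to the S1 reference over one replicate."""

    replicate_id: int
    ion_id: str
    species: str
    times: np.ndarray
    distances: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "distances", d)
        if t.ndim != 1 or t.shape != d.shape:
            raise ValueError("times and distances must be equal-length 1-D arrays")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError(f"times must be strictly increasing for ion {self.ion_id}")
        if np.any(d < 0):
            raise ValueError(f"negative distance in series for ion {self.ion_id}")

    @property
    def role(self) -> int:
        """Ion role number (1 = outermost at S1, 4 = innermost tracked ion)."""
        digits = "".join(ch for ch in self.ion_id if ch.isdigit())
        if not digits:
            raise ValueError(f"ion_id {self.ion_id!r} carries no role number")
        return int(digits)

    def __len__(self) -> int:
        return self.times.size


def series_to_frame(series: Iterable[IonDistanceSeries]) -> pd.DataFrame:
    """Flatten series into the tabular interchange format."""
    parts = []
    for s in series:
        parts.append(
            pd.DataFrame(
                {
                    "replicate": s.replicate_id,
                    "time_ns": s.times,
                    "ion_id": s.ion_id,
                    "species": s.species,
                    "distance_A": s.distances,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    return pd.concat(parts, ignore_index=True)


def read_ion_distance_table(
    path: str | Path, *, uniformity_rtol: float = 1e-6
) -> list[IonDistanceSeries]:
    """Read a trajectory distance table (TSV or CSV) into per-ion series.

    One series is produced per ``(replicate, ion_id)``.  Rows may appear in
    any order; they are sorted by time.  Duplicate ``(replicate, ion_id,
    time_ns)`` rows and non-uniform sampling are rejected with the offending
    line numbers (1-based, header included).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    bad = df[list(REQUIRED_COLUMNS[:2])].isna().any(axis=1) | df["distance_A"].isna()
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad][:10]]
        raise ValueError(f"{path}: malformed rows at lines {lines}")

    dup = df.duplicated(subset=["replicate", "ion_id", "time_ns"], keep=False)
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup][:10]]
        raise ValueError(
            f"{path}: duplicate (replicate, ion_id, time_ns) rows at lines {lines}"
        )

    out: list[IonDistanceSeries] = []
    for (rep, ion), grp in df.groupby(["replicate", "ion_id"], sort=True):
        grp = grp.sort_values("time_ns")
        t = grp["time_ns"].to_numpy(dtype=float)
        if t.size >= 3:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=uniformity_rtol, atol=0.0):
                raise ValueError(
                    f"{path}: non-uniform sampling for replicate {rep}, ion {ion} "
                    f"(step range {dt.min():g}..{dt.max():g} ns)"
                )
        out.append(
            IonDistanceSeries(
                replicate_id=int(rep),
                ion_id=str(ion),
                species=str(grp["species"].iloc[0]),
                times=t,
                distances=grp["distance_A"].to_numpy(dtype=float),
            )
        )
    return out


@dataclass(frozen=True)
class ExclusionReport:
    n_retained: int
    n_excluded: int
    per_ion: pd.DataFrame  # columns ion_id, n_retained, n_excluded
    threshold_A: float
    s4_offset_A: float

    @property
    def n_total(self) -> int:
        return self.n_retained + self.n_excluded


def apply_sf_exclusion(
    series: Sequence[IonDistanceSeries],
    threshold: float = 5.0,
    *,
    s4_offset: float = DEFAULT_SITE_MAP["S4"],
    inner_role: int | None = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop records of boundary ions that have left the selectivity filter.

    The outermost ion (role 1) is judged against the S1 reference directly: a
    distance above ``threshold`` indicates an extracellular leave.  The
    innermost ion (highest role present) is judged against the S4-forming
    residue; since only the S1-referenced distance column exists, its distance
    to S4 is derived as ``|distance - s4_offset|``.  Individual records are
    removed, never whole frames; ions with intermediate roles are always
    retained.

    Returns the retained records as a tidy frame plus an
    :class:`ExclusionReport` with per-ion counts.
    """
    if threshold <= 0:
        raise ValueError("exclusion threshold must be positive")
    if not series:
        raise ValueError("no series supplied")
    if inner_role is None:
        inner_role = max(s.role for s in series)

    frames, rows = [], []
    for s in series:
        d = s.distances
        if s.role == 1:
            keep = d <= threshold
        elif s.role == inner_role and inner_role != 1:
            keep = np.abs(d - s4_offset) <= threshold
        else:
            keep = np.ones_like(d, dtype=bool)
        rows.append((s.ion_id, int(keep.sum()), int((~keep).sum())))
        frames.append(
            pd.DataFrame(
                {
                    "replicate": s.replicate_id,
                    "time_ns": s.times[keep],
                    "ion_id": s.ion_id,
                    "species": s.species,
                    "distance_A": d[keep],
                }
            )
        )
    retained = pd.concat(frames, ignore_index=True)
    per_ion = (
        pd.DataFrame(rows, columns=["ion_id", "n_retained", "n_excluded"])
        .groupby("ion_id", as_index=False)
        .sum()
    )
    report = ExclusionReport(
        n_retained=int(per_ion["n_retained"].sum()),
        n_excluded=int(per_ion["n_excluded"].sum()),
        per_ion=per_ion,
        threshold_A=float(threshold),
        s4_offset_A=float(s4_offset),
    )
    return retained, report


@dataclass(frozen=True)
class OccupancyHistogram:
    """Relative count of ion presence along the filter axis."""

    bin_edges: np.ndarray
    counts: np.ndarray
    relative: np.ndarray
    overflow: int
    label: str = ""

    @property
    def n_binned(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "count": self.counts,
                "relative": self.relative,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_occupancy_tsv(path: str | Path, *, label: str = "") -> OccupancyHistogram:
    """Re-read a histogram TSV written by :meth:`OccupancyHistogram.write_tsv`."""
    df = pd.read_csv(path, sep="\t")
    edges = np.concatenate([df["bin_lo"].to_numpy(), [df["bin_hi"].iloc[-1]]])
    counts = df["count"].to_numpy()
    return OccupancyHistogram(
        bin_edges=edges,
        counts=counts,
        relative=df["relative"].to_numpy(),
        overflow=0,
        label=label or str(path),
    )


def compute_occupancy_histogram(
    records: pd.DataFrame | np.ndarray,
    n_bins: int = 50,
    value_range: tuple[float, float] = (0.0, 16.0),
    *,
    label: str = "",
) -> OccupancyHistogram:
    """Bin retained distance records into a relative occupancy histogram.

    Bins are left-closed/right-open except the last, which also includes the
    right edge (the ``numpy.histogram`` convention).  Records outside
    ``value_range`` are tallied in ``overflow`` and never binned, so the
    relative counts always sum to one over the binned records.
    """
    if isinstance(records, pd.DataFrame):
        d = records["distance_A"].to_numpy(dtype=float)
    else:
        d = np.asarray(records, dtype=float)
    if d.size == 0:
        raise ValueError("empty record set")
    lo, hi = value_range
    counts, edges = np.histogram(d, bins=n_bins, range=value_range)
    overflow = int(((d < lo) | (d > hi)).sum())
    total = counts.sum()
    relative = counts / total if total > 0 else np.zeros_like(counts, dtype=float)
    return OccupancyHistogram(
        bin_edges=edges,
        counts=counts,
        relative=relative,
        overflow=overflow,
        label=label,
    )


@dataclass(frozen=True)
class DeltaHistogram:
    bin_edges: np.ndarray
    delta: np.ndarray
    label_a: str = ""
    label_b: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "delta_relative": self.delta,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def compare_occupancy(
    hist_a: OccupancyHistogram, hist_b: OccupancyHistogram
) -> DeltaHistogram:
    """Per-bin difference ``relative_b - relative_a``.

    Positive values mean higher probability of ion presence in condition *b*
    (conventionally the mutant).  Both inputs are normalized, so the deltas
    sum to zero.
    """
    if hist_a.bin_edges.shape != hist_b.bin_edges.shape or not np.array_equal(
        hist_a.bin_edges, hist_b.bin_edges
    ):
        raise ValueError("histograms have mismatched bin edges")
    return DeltaHistogram(
        bin_edges=hist_a.bin_edges.copy(),
        delta=hist_b.relative - hist_a.relative,
        label_a=hist_a.label,
        label_b=hist_b.label,
    )


def _ordered_sites(site_map: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    labels = list(site_map)
    pos = np.array([site_map[k] for k in labels], dtype=float)
    order = np.argsort(pos)
    labels = [labels[i] for i in order]
    pos = pos[order]
    if np.any(np.diff(pos) <= 0):
        raise ValueError("site_map distances must be strictly ordered")
    return labels, pos


def assign_sites(
    distances: np.ndarray | float,
    site_map: Mapping[str, float] = DEFAULT_SITE_MAP,
    hysteresis: float = 0.5,
) -> np.ndarray | str:
    """Assign each distance to a ladder site with flicker suppression.

    A site's *core* region extends from the midpoint toward its inner
    neighbour to the midpoint toward its outer neighbour, each shrunk by half
    the hysteresis band.  A sample inside a core adopts that site; a sample in
    the dead band between cores keeps the previous assignment.  The first
    sample falls back to the nearest site.  Scalars map to the nearest site.
    """
    labels, pos = _ordered_sites(site_map)
    if hysteresis < 0:
        raise ValueError("hysteresis must be non-negative")
    mids = (pos[:-1] + pos[1:]) / 2.0
    # every site must remain inside its own core region
    if pos.size >= 2 and np.any(np.diff(pos) <= hysteresis):
        raise ValueError("hysteresis bands overlap between adjacent sites")

    scalar = np.isscalar(distances)
    d = np.atleast_1d(np.asarray(distances, dtype=float))

    lo = np.concatenate(([-np.inf], mids + hysteresis / 2.0))
    hi = np.concatenate((mids - hysteresis / 2.0, [np.inf]))
    # core index per sample, -1 when in a dead band
    core = np.full(d.size, -1, dtype=int)
    for i in range(len(labels)):
        core[(d > lo[i]) & (d < hi[i])] = i

    out = np.empty(d.size, dtype=int)
    prev = int(np.argmin(np.abs(pos - d[0])))
    for k in range(d.size):
        if core[k] >= 0:
            prev = core[k]
        out[k] = prev
    result = np.array(labels, dtype=object)[out]
    if scalar:
        return str(result[0])
    return result


@dataclass(frozen=True)
class TransitionTable:
    """First-passage times of the tracked ion through the four filter steps."""

    replicate_id: int
    ion_id: str
    times_ns: tuple[float | None, float | None, float | None, float | None]
    censored: tuple[bool, bool, bool, bool]

    def __post_init__(self) -> None:
        achieved = [t for t in self.times_ns if t is not None]
        if any(b - a <= 0 for a, b in zip(achieved, achieved[1:]) if b != a) and not all(
            b >= a for a, b in zip(achieved, achieved[1:])
        ):
            raise ValueError("achieved transition times must be non-decreasing")


def detect_transitions(
    tracked: IonDistanceSeries,
    site_map: Mapping[str, float] = DEFAULT_SITE_MAP,
    hysteresis: float = 0.5,
    *,
    exit_site: str = "out",
) -> TransitionTable:
    """First-passage detection of the four permeation steps of the lowest ion.

    Transition *k* is the first time the hysteresis-assigned site reaches the
    *k*-th station above S4 in conduction order (S3, S2, S1, out of the
    filter).  Back-steps never erase an achieved transition; stations skipped
    between samples are credited at the time the farther station is first
    seen.  The exit station (distances beyond the cavity on the analysis
    axis, where the generator parks extracellularly departed ions) counts
    only when the preceding in-filter assignment was in the outer filter
    (S3 or above), so an inward departure into the cavity bulk is not
    mistaken for a permeation.  Steps not reached by the end of the series
    are censored.
    """
    if len(tracked) < 2:
        raise ValueError("series must hold at least 2 samples")
    full_map = dict(site_map)
    if exit_site not in full_map:
        # exit station sits just past the cavity end of the axis
        full_map[exit_site] = max(site_map.values()) + 2.5
    sites = assign_sites(tracked.distances, full_map, hysteresis)
    order = {lab: PERMEATION_ORDER.index(lab) for lab in ("S4", "S3", "S2", "S1")}
    order[exit_site] = PERMEATION_ORDER.index("out")
    order["cavity"] = PERMEATION_ORDER.index("cavity")

    stations = ["S3", "S2", "S1", exit_site]
    times: list[float | None] = [None, None, None, None]
    nxt = 0
    prev_in_filter = None
    for t, lab in zip(tracked.times, sites):
        rank = order.get(lab)
        if rank is None:
            continue
        if lab == exit_site:
            # outward exit: ion last seen in the outer filter; stations
            # skipped between samples are credited at the exit time
            if prev_in_filter in ("S1", "S2", "S3"):
                while nxt < 4:
                    times[nxt] = float(t)
                    nxt += 1
        else:
            while nxt < 3 and rank >= order[stations[nxt]]:
                times[nxt] = float(t)
                nxt += 1
            prev_in_filter = lab
        if nxt == 4:
            break
    censored = tuple(t is None for t in times)
    return TransitionTable(
        replicate_id=tracked.replicate_id,
        ion_id=tracked.ion_id,
        times_ns=tuple(times),
        censored=censored,
    )


@dataclass(frozen=True)
class PermeationSummary:
    """Mean +/- SEM first-passage times over replicates, with censoring."""

    table: pd.DataFrame  # transition, n_achieved, n_censored, mean_ns, sem_ns

    def to_json_dict(self) -> dict:
        recs = self.table.to_dict(orient="records")
        for r in recs:
            for k, v in list(r.items()):
                if isinstance(v, float) and math.isnan(v):
                    r[k] = None
        return {"transitions": recs}


def summarize_permeation(tables: Sequence[TransitionTable]) -> PermeationSummary:
    """Summarize per-transition first-passage times across replicates.

    Means and SEMs are computed over the replicates that achieved a given
    transition (SEM with n-1 denominator, defined only for n >= 2); censored
    replicates are counted alongside, never imputed.
    """
    if not tables:
        raise ValueError("at least one replicate required")
    rows = []
    for k in range(4):
        vals = np.array(
            [t.times_ns[k] for t in tables if t.times_ns[k] is not None], dtype=float
        )
        n_a = vals.size
        n_c = len(tables) - n_a
        mean = float(vals.mean()) if n_a >= 1 else float("nan")
        sem = float(vals.std(ddof=1) / math.sqrt(n_a)) if n_a >= 2 else float("nan")
        rows.append((k + 1, n_a, n_c, mean, sem))
    return PermeationSummary(
        table=pd.DataFrame(
            rows, columns=["transition", "n_achieved", "n_censored", "mean_ns", "sem_ns"]
        )
    )
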