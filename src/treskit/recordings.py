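"""Sweep containers and schedule-aware measurement helpers for TEVC data.

:class:`SweepSet` binds tabular sweep samples (sweep index, time, command
voltage, current) to the :class:`~treskit.protocols.ProtocolSchedule` that
produced them.  The helpers below walk a sweep set according to its
schedule and extract the quantities the pharmacological analysis consumes:
per-block steady-state currents, screening potentiation, dose-response
activities, IV tables, and tail/steady inactivation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ephys import compute_activity, compute_FI, compute_potentiation, fit_exponential_tau, measure_current
from .protocols import ProtocolSchedule

__all__ = [
    "SweepSet",
    "read_sweep_table",
    "block_current",
    "screening_potentiation",
    "dose_response_activities",
    "iv_table",
    "inactivation_table",
]

SWEEP_COLUMNS = ("sweep_index", "time_ms", "voltage_mV", "current_uA")


@dataclass(frozen=True)
class SweepSet:
    """Sampled sweeps of one cell, bound to their protocol schedule."""

    data: pd.DataFrame  # sweep_index (1-based), time_ms, voltage_mV, current_uA
    schedule: ProtocolSchedule
    cell_id: str = "cell-1"

    def __post_init__(self) -> None:
        missing = [c for c in SWEEP_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"sweep data missing columns {missing}")
        if int(self.data["sweep_index"].max()) > self.schedule.n_sweeps:
            raise ValueError("more sweeps than the schedule defines")

    @property
    def n_sweeps(self) -> int:
        return int(self.data["sweep_index"].max())

    def sweep(self, index: int) -> pd.DataFrame:
        out = self.data[self.data["sweep_index"] == index]
        if out.empty:
            raise KeyError(f"no sweep {index}")
        return out.reset_index(drop=True)

    def write_csv(self, path: str | Path) -> None:
        path = Path(path)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        self.data.to_csv(path, sep=sep, index=False)


def read_sweep_table(path: str | Path, schedule: ProtocolSchedule) -> SweepSet:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    return SweepSet(data=df, schedule=schedule)


def _target_segment(schedule: ProtocolSchedule, sweep_index: int) -> int:
    """Index of the most hyperpolarized segment of a sweep (the test pulse)."""
    segs = schedule.sweeps[sweep_index - 1]
    return int(np.argmin([s.voltage_mV for s in segs]))


def block_current(
    sweeps: SweepSet,
    block_label: str,
    *,
    n_last: int = 3,
    window: str = "steady_state",
    **window_kw,
) -> float:
    """Mean test-pulse current (uA) over the last ``n_last`` sweeps of a block."""
    block = next(
        (b for b in sweeps.schedule.blocks if b.label == block_label), None
    )
    if block is None:
        raise KeyError(f"no solution block {block_label!r}")
    first = max(block.first_sweep, block.last_sweep - n_last + 1)
    vals = []
    for i in range(first, block.last_sweep + 1):
        k = _target_segment(sweeps.schedule, i)
        lo, hi = sweeps.schedule.segment_bounds_ms(i, k)
        vals.append(measure_current(sweeps.sweep(i), lo, hi, window, **window_kw))
    return float(np.mean(vals))


def screening_potentiation(sweeps: SweepSet, *, n_last: int = 3) -> float:
    """Current potentiation I_cmp / I_ctrl from a screening recording.

    Quasi-steady-state currents are taken from the last sweeps of the
    high-K control block and of the compound block, at the hyperpolarizing
    test pulse.
    """
    i_ctrl = block_current(sweeps, "high_K_control", n_last=n_last)
    i_cmp = block_current(sweeps, "compound", n_last=n_last)
    return compute_potentiation(i_cmp, i_ctrl)


def dose_response_activities(sweeps: SweepSet, *, n_last: int = 3) -> pd.DataFrame:
    """Percent activity per concentration block of a dose-response recording."""
    ctrl = block_current(sweeps, "high_K_control", n_last=n_last)
    rows = []
    for b in sweeps.schedule.blocks:
        if b.compound_uM <= 0:
            continue
        i_cmp = block_current(sweeps, b.label, n_last=n_last)
        rows.append((b.compound_uM, compute_activity(i_cmp, ctrl)))
    if not rows:
        raise ValueError("schedule contains no compound blocks")
    return pd.DataFrame(rows, columns=["conc_uM", "activity_pct"])


def iv_table(sweeps: SweepSet) -> pd.DataFrame:
    """Steady-state current per voltage step for the control and compound phases.

    Expects an IV-kind schedule whose step sweeps hold a single segment each.
    Returns columns ``condition`` (control/compound), ``voltage_mV``,
    ``current_uA``.
    """
    rows = []
    for b in sweeps.schedule.blocks:
        if not b.label.startswith("iv_"):
            continue
        condition = b.label.removeprefix("iv_")
        for i in range(b.first_sweep, b.last_sweep + 1):
            segs = sweeps.schedule.sweeps[i - 1]
            if len(segs) != 1:
                raise ValueError("IV step sweeps must hold a single segment")
            lo, hi = sweeps.schedule.segment_bounds_ms(i, 0)
            cur = measure_current(sweeps.sweep(i), lo, hi, "steady_state")
            rows.append((condition, segs[0].voltage_mV, cur))
    if not rows:
        raise ValueError("schedule contains no IV blocks")
    return pd.DataFrame(rows, columns=["condition", "voltage_mV", "current_uA"])


def inactivation_table(
    sweeps: SweepSet, *, fit_tau: bool = True, tail_delay_ms: float = 2.0
) -> pd.DataFrame:
    """Per-sweep F_I (and optional tau) for an inactivation recording.

    For every sweep the tail and steady-state currents of the
    hyperpolarizing test pulse give ``F_I``; the decaying stretch of the
    pulse is optionally fitted to a single exponential for the per-trace
    time constant.  The inter-pulse duration is read off the schedule (the
    depolarizing segment immediately before the test pulse).
    """
    rows = []
    for b in sweeps.schedule.blocks:
        condition = b.label
        for i in range(b.first_sweep, b.last_sweep + 1):
            k = _target_segment(sweeps.schedule, i)
            if sweeps.schedule.sweeps[i - 1][k].voltage_mV > -90.0:
                continue  # holding/wash-in sweep without a test pulse
            lo, hi = sweeps.schedule.segment_bounds_ms(i, k)
            sweep = sweeps.sweep(i)
            i_tail = measure_current(sweep, lo, hi, "tail", tail_delay_ms=tail_delay_ms)
            i_steady = measure_current(sweep, lo, hi, "steady_state")
            fi = compute_FI(i_tail, i_steady)
            dur = sweeps.schedule.sweeps[i - 1][k - 1].duration_ms if k > 0 else np.nan
            tau = np.nan
            if fit_tau:
                t = sweep["time_ms"].to_numpy()
                mask = (t >= lo + tail_delay_ms) & (t < hi)
                fit = fit_exponential_tau(t[mask], sweep["current_uA"].to_numpy()[mask])
                if fit.identifiable:
                    tau = fit.tau
            rows.append((condition, float(dur), fi, tau))
    return pd.DataFrame(rows, columns=["condition", "duration_ms", "fi_pct", "tau_ms"])
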