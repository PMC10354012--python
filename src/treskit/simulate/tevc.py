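"""Surrogate generator of two-electrode voltage-clamp sweep recordings.

Per-sweep current traces follow

    I(t) = g * r(V) * (V - E_rev) * P(t) * A(t) + I_cap(t) + noise

with conductance ``g``, an outward rectification factor ``r`` applied above
the reversal potential, the Nernst reversal potential ``E_rev`` derived from
the internal and bath ion concentrations of the active solution block, a
compound wash-in potentiation state ``P``, a hyperpolarization-induced
selectivity-filter inactivation state ``A``, a fast capacitive transient at
every voltage-step edge, and Gaussian recording noise.

Wash-in is biphasic: a fast saturating component plus a slow component whose
onset is delayed, which produces the temporary plateau seen between the two
phases of compound application.  Inactivation during a hyperpolarizing test
pulse decays exponentially to a steady state whose extent grows with the
duration of the preceding depolarization as ``F_I = a - b * c^x``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..ephys import nernst_potential
from ..protocols import ProtocolSchedule
from ..recordings import SweepSet
from .dose_response import DoseResponseModelSpec, predict_activity

__all__ = [
    "EphysSimConfig",
    "simulate_tevc_recording",
    "biphasic_washin",
]


def biphasic_washin(
    t_s: np.ndarray | float,
    amplitudes: tuple[float, float] = (0.8, 0.7),
    tau_s: tuple[float, float] = (5.0, 30.0),
    delay_s: float = 15.0,
) -> np.ndarray | float:
    """Potentiation factor P(t) after a compound application starting at t = 0.

    Fast component immediately, slow component after ``delay_s``; the sum
    saturates at ``1 + a_fast + a_slow``.  Between the fast and the delayed
    slow phase the slope dips, yielding the quasi-plateau of a biphasic
    wash-in.
    """
    t = np.asarray(t_s, dtype=float)
    a1, a2 = amplitudes
    t1, t2 = tau_s
    p = 1.0 + a1 * (1.0 - np.exp(-np.clip(t, 0, None) / t1))
    td = np.clip(t - delay_s, 0, None)
    p = p + a2 * (1.0 - np.exp(-td / t2)) * (t >= delay_s)
    return p if p.ndim else float(p)


@dataclass(frozen=True)
class EphysSimConfig:
    """Parameters of the sweep-current surrogate.

    ``dose_model`` (when given) sets the saturated wash-in amplitude of a
    compound block from the closed-form activity at the block concentration;
    otherwise ``washin_amplitudes`` applies to every compound block
    regardless of concentration.  Setting ``fi_a = fi_b = 0`` disables
    inactivation; ``capacitance_uA_per_mV = 0`` disables step transients.
    """

    schedule: ProtocolSchedule
    ion_in_mM: float = 100.0
    temperature_C: float = 20.0
    conductance_uS: float = 0.05
    rectification_factor: float = 2.0
    washin_amplitudes: tuple[float, float] = (0.8, 0.7)
    washin_tau_s: tuple[float, float] = (5.0, 30.0)
    washin_delay_s: float = 15.0
    washin_fractions: tuple[float, float] = (0.55, 0.45)
    dose_model: DoseResponseModelSpec | None = None
    fi_a: float = 15.9  # steady-state inactivated fraction, %
    fi_b: float = 15.9
    fi_c_per_ms: float = 0.98
    fi_tau_ms: float = 50.0
    fi_compound_factor: float = 0.7  # compound-induced reduction of F_I
    hyper_threshold_mV: float = -50.0
    depol_threshold_mV: float = 0.0
    capacitance_uA_per_mV: float = 0.005
    cap_tau_ms: float = 1.0
    noise_sd_uA: float = 0.02
    sample_interval_ms: float = 1.0
    cell_id: str = "cell-1"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.washin_tau_s) or self.fi_tau_ms <= 0:
            raise ValueError("time constants must be positive")
        if not (0.0 <= self.fi_a <= 100.0):
            raise ValueError("steady-state inactivated fraction must be in [0, 100]%")
        if self.sample_interval_ms <= 0 or self.noise_sd_uA < 0:
            raise ValueError("invalid sampling or noise parameters")
        if abs(sum(self.washin_fractions) - 1.0) > 1e-9:
            raise ValueError("washin_fractions must sum to 1")


class _Relaxation:
    """Piecewise-exponential relaxation toward a stepwise-switching target."""

    def __init__(self, tau_s: float):
        self.tau = tau_s
        self.events: list[tuple[float, float, float]] = [(0.0, 0.0, 0.0)]
        # (switch time, value at switch, target)

    def switch(self, t: float, target: float) -> None:
        self.events.append((t, self.value(t), target))

    def value(self, t: float | np.ndarray):
        times = np.array([e[0] for e in self.events])
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(times, t_arr, side="right") - 1
        v0 = np.array([self.events[i][1] for i in idx])
        tgt = np.array([self.events[i][2] for i in idx])
        dt = t_arr - times[idx]
        out = tgt + (v0 - tgt) * np.exp(-dt / self.tau)
        return out if np.ndim(t) else float(out[0])


def _block_amplitude(config: EphysSimConfig, compound_uM: float) -> float:
    if compound_uM <= 0:
        return 0.0
    if config.dose_model is not None:
        return float(predict_activity(config.dose_model, [compound_uM])[0]) / 100.0
    return sum(config.washin_amplitudes)


def simulate_tevc_recording(config: EphysSimConfig) -> SweepSet:
    """Simulate every sweep of the schedule into a :class:`SweepSet`.

    The potentiation state evolves continuously across sweep boundaries: at
    each solution-block change the fast component re-targets immediately and
    the slow component after the configured onset delay, for wash-in and
    washout alike.  The inactivation state resets at each sweep start and
    develops only during hyperpolarizing segments, to an extent set by the
    immediately preceding depolarization duration within the sweep.
    """
    sched = config.schedule
    rng = np.random.default_rng(config.seed)
    f1, f2 = config.washin_fractions
    fast = _Relaxation(config.washin_tau_s[0])
    slow = _Relaxation(config.washin_tau_s[1])

    prev_amp = 0.0
    for block in sched.blocks:
        amp = _block_amplitude(config, block.compound_uM)
        if amp != prev_amp:
            t0 = sched.sweep_start_s(block.first_sweep)
            fast.switch(t0, f1 * amp)
            slow.switch(t0 + config.washin_delay_s, f2 * amp)
            prev_amp = amp

    dt = config.sample_interval_ms
    records = []
    prev_voltage: float | None = None
    for i in range(1, sched.n_sweeps + 1):
        block = sched.block_of(i)
        e_rev = nernst_potential(config.ion_in_mM, block.k_out_mM, config.temperature_C)
        segs = sched.sweeps[i - 1]
        period_ms = sum(s.duration_ms for s in segs)
        n = int(round(period_ms / dt))
        t_ms = np.arange(n) * dt
        sweep_t0 = sched.sweep_start_s(i)

        bounds = np.cumsum([0.0] + [s.duration_ms for s in segs])
        seg_idx = np.clip(np.searchsorted(bounds, t_ms, side="right") - 1, 0, len(segs) - 1)
        volt = np.array([segs[k].voltage_mV for k in seg_idx])

        drive = volt - e_rev
        rect = np.where(volt > e_rev, config.rectification_factor, 1.0)
        p = 1.0 + fast.value(sweep_t0 + t_ms / 1000.0) + slow.value(
            sweep_t0 + t_ms / 1000.0
        )

        # inactivation state, per hyperpolarizing segment
        a_state = np.ones(n)
        if config.fi_b > 0 or config.fi_a > 0:
            factor = 1.0
            if block.compound_uM > 0:
                occ = 1.0
                if config.dose_model is not None:
                    dm = config.dose_model
                    occ = block.compound_uM**dm.hill / (
                        block.compound_uM**dm.hill + dm.ec50**dm.hill
                    )
                # filter stabilization scales with receptor occupancy
                factor = 1.0 - (1.0 - config.fi_compound_factor) * occ
            for k, seg in enumerate(segs):
                if seg.voltage_mV > config.hyper_threshold_mV:
                    continue
                x = 0.0
                for j in range(k - 1, -1, -1):
                    if segs[j].voltage_mV >= config.depol_threshold_mV:
                        x += segs[j].duration_ms
                    else:
                        break
                fi = max(0.0, min(100.0, (config.fi_a - config.fi_b * config.fi_c_per_ms**x)))
                fi *= factor
                mask = seg_idx == k
                t_in = t_ms[mask] - bounds[k]
                a_state[mask] = (1.0 - fi / 100.0) + (fi / 100.0) * np.exp(
                    -t_in / config.fi_tau_ms
                )

        current = config.conductance_uS * rect * drive * p * a_state

        if config.capacitance_uA_per_mV > 0:
            edges = []
            if prev_voltage is not None and segs[0].voltage_mV != prev_voltage:
                edges.append((0.0, segs[0].voltage_mV - prev_voltage))
            for k in range(1, len(segs)):
                dv = segs[k].voltage_mV - segs[k - 1].voltage_mV
                if dv != 0:
                    edges.append((bounds[k], dv))
            for t_edge, dv in edges:
                after = t_ms >= t_edge
                current[after] += (
                    config.capacitance_uA_per_mV
                    * dv
                    * np.exp(-(t_ms[after] - t_edge) / config.cap_tau_ms)
                )
        prev_voltage = segs[-1].voltage_mV

        if config.noise_sd_uA > 0:
            current = current + rng.normal(0.0, config.noise_sd_uA, size=n)

        records.append(
            pd.DataFrame(
                {
                    "sweep_index": i,
                    "time_ms": t_ms,
                    "voltage_mV": volt,
                    "current_uA": current,
                }
            )
        )
    data = pd.concat(records, ignore_index=True)
    return SweepSet(data=data, schedule=sched, cell_id=config.cell_id)
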