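"""Two-electrode voltage-clamp analysis: measurement, pharmacology, kinetics.

The analysis chain implemented here mirrors standard oocyte TEVC practice
for K2P-channel pharmacology:

* window-based current measurement (steady-state and post-step tail windows),
* per-cell current potentiation ``I_cmp / I_ctrl`` and percent activity
  ``(I_cmp / I_ctrl - 1) * 100``,
* IV normalization to the +40 mV control current of the same cell,
* Hill dose-response fitting with the minimal activity fixed at zero,
* binding-site stoichiometry comparison (proportional-occupancy versus
  single-site-sufficient) and competitive-versus-noncompetitive antagonism
  classification from families of Hill fits,
* selectivity-filter inactivation statistics: the inactivated fraction
  F_I = (1 - I_steady / I_tail) * 100, its asymptotic growth with
  depolarization duration F_I = a - b * c^x, and single-exponential decay
  fits y = a0 + a1 * exp(-x / tau),
* group statistics (one-way ANOVA with Tukey HSD, two-sided t-test, SEM,
  significance stars).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lmfit import Model, Parameters
from scipy import stats as sps

__all__ = [
    "nernst_potential",
    "measure_current",
    "compute_potentiation",
    "compute_activity",
    "normalize_iv",
    "HillFit",
    "fit_hill",
    "StoichiometryReport",
    "compare_stoichiometry",
    "AntagonismReport",
    "classify_antagonism",
    "compute_FI",
    "GrowthFit",
    "fit_inactivation_growth",
    "ExponentialFit",
    "fit_exponential_tau",
    "StatsReport",
    "group_stats",
    "significance_stars",
]

R_GAS = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol


def nernst_potential(
    c_in_mM: float, c_out_mM: float, temperature_C: float = 20.0, z: int = 1
) -> float:
    """Nernst reversal potential in mV for a monovalent-by-default ion."""
    if c_in_mM <= 0 or c_out_mM <= 0:
        raise ValueError("concentrations must be positive")
    T = temperature_C + 273.15
    return 1000.0 * R_GAS * T / (z * FARADAY) * math.log(c_out_mM / c_in_mM)


# ----------------------------------------------------------------------------
# current measurement


def measure_current(
    sweep: pd.DataFrame,
    segment_start_ms: float,
    segment_end_ms: float,
    window: str = "steady_state",
    *,
    steady_window_ms: float = 50.0,
    tail_delay_ms: float = 2.0,
    tail_width_ms: float = 5.0,
) -> float:
    """Measure a segment current (uA) in a configurable window.

    ``steady_state`` averages the final ``steady_window_ms`` of the segment;
    ``tail`` averages ``tail_width_ms`` starting ``tail_delay_ms`` after the
    segment onset, skipping the capacitive transient at the step edge.
    Windows that would extend past the segment bounds are rejected.
    """
    if segment_end_ms <= segment_start_ms:
        raise ValueError("empty segment")
    seg_len = segment_end_ms - segment_start_ms
    if window == "steady_state":
        if steady_window_ms <= 0 or steady_window_ms > seg_len:
            raise ValueError("steady-state window outside segment bounds")
        lo, hi = segment_end_ms - steady_window_ms, segment_end_ms
    elif window == "tail":
        if tail_delay_ms < 0 or tail_width_ms <= 0:
            raise ValueError("invalid tail window")
        if tail_delay_ms + tail_width_ms > seg_len:
            raise ValueError("tail window outside segment bounds")
        lo = segment_start_ms + tail_delay_ms
        hi = lo + tail_width_ms
    else:
        raise ValueError(f"unknown window {window!r}")
    t = sweep["time_ms"].to_numpy()
    mask = (t >= lo) & (t < hi)
    if not mask.any():
        raise ValueError("no samples inside measurement window")
    return float(sweep["current_uA"].to_numpy()[mask].mean())


def compute_potentiation(i_cmp: float, i_ctrl: float) -> float:
    """Per-cell current potentiation ``I_cmp / I_ctrl`` (same voltage, paired)."""
    if i_ctrl == 0:
        raise ValueError("zero control current")
    if i_cmp != 0 and (i_cmp > 0) != (i_ctrl > 0):
        raise ValueError("current sign mismatch between compound and control")
    ratio = i_cmp / i_ctrl
    if ratio < 1.0:
        warnings.warn(f"potentiation ratio {ratio:.3g} < 1 (inhibition)", stacklevel=2)
    return ratio


def compute_activity(i_cmp: float, i_ctrl: float) -> float:
    """Percent activity ``(I_cmp / I_ctrl - 1) * 100``; negative = inhibition."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ratio = compute_potentiation(i_cmp, i_ctrl)
    return (ratio - 1.0) * 100.0


def normalize_iv(
    currents: pd.DataFrame, reference_voltage_mV: float = 40.0
) -> pd.DataFrame:
    """Normalize IV currents of one cell to its control current at +40 mV.

    ``currents`` needs columns ``voltage_mV``, ``current_uA`` and
    ``condition`` (``control`` / anything else).  All currents, with and
    without compound, are divided by the control current at the reference
    voltage, making curves from different cells comparable.
    """
    ref_rows = currents[
        (currents["condition"] == "control")
        & np.isclose(currents["voltage_mV"], reference_voltage_mV)
    ]
    if ref_rows.empty:
        raise ValueError(f"no control current at {reference_voltage_mV:g} mV")
    ref = float(ref_rows["current_uA"].mean())
    if ref == 0:
        raise ValueError("zero reference current")
    out = currents.copy()
    out["current_norm"] = out["current_uA"] / ref
    return out


# ----------------------------------------------------------------------------
# Hill dose-response fitting


def _hill(x, e_max, ec50, h):
    return e_max * x**h / (x**h + ec50**h)


@dataclass(frozen=True)
class HillFit:
    """Hill-equation fit with the minimal activity fixed at zero."""

    e_max: float
    ec50: float
    h: float
    se_e_max: float | None
    se_ec50: float | None
    se_h: float | None
    residual_ss: float
    n_points: int
    converged: bool

    def predict(self, conc: np.ndarray | float) -> np.ndarray | float:
        return _hill(np.asarray(conc, dtype=float), self.e_max, self.ec50, self.h)


def fit_hill(data: pd.DataFrame) -> HillFit:
    """Nonlinear least-squares Hill fit of pooled activity points.

    ``data`` needs columns ``conc_uM`` and ``activity_pct``.  Initialization:
    E_max at the maximal observed activity, EC50 at the geometric mean of the
    concentration range, h = 1.  Standard errors come from the covariance at
    the optimum; a fit that does not converge is returned flagged, never
    silently.
    """
    c = data["conc_uM"].to_numpy(dtype=float)
    y = data["activity_pct"].to_numpy(dtype=float)
    if np.unique(c).size < 4:
        raise ValueError("at least 4 distinct concentrations required")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    model = Model(_hill)
    params = Parameters()
    params.add("e_max", value=max(float(y.max()), 1e-6))
    params.add("ec50", value=float(math.sqrt(c.min() * c.max())), min=1e-12)
    params.add("h", value=1.0, min=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(y, params, x=c)
    p = result.params
    return HillFit(
        e_max=float(p["e_max"].value),
        ec50=float(p["ec50"].value),
        h=float(p["h"].value),
        se_e_max=None if p["e_max"].stderr is None else float(p["e_max"].stderr),
        se_ec50=None if p["ec50"].stderr is None else float(p["ec50"].stderr),
        se_h=None if p["h"].stderr is None else float(p["h"].stderr),
        residual_ss=float(np.sum(result.residual**2)),
        n_points=int(c.size),
        converged=bool(result.success),
    )


def _ratio_with_se(
    num: float, num_se: float | None, den: float, den_se: float | None
) -> tuple[float, float]:
    ratio = num / den
    n_se = 0.0 if num_se is None else num_se
    d_se = 0.0 if den_se is None else den_se
    se = abs(ratio) * math.sqrt((n_se / num) ** 2 + (d_se / den) ** 2)
    return ratio, se


def _z_p(value: float, null: float, se: float) -> float:
    """Two-sided normal p-value; a vanishing SE degenerates to exact comparison."""
    se = max(se, 1e-9 * max(abs(value), abs(null), 1.0))
    z = (value - null) / se
    return 2.0 * (1.0 - sps.norm.cdf(abs(z)))


@dataclass(frozen=True)
class StoichiometryReport:
    e_max_ratio: float
    e_max_ratio_se: float
    ec50_ratio: float
    ec50_ratio_se: float
    p_e_max_vs_one: float
    p_e_max_vs_half: float
    p_ec50_vs_one: float
    classification: str


def compare_stoichiometry(
    fit_ref: HillFit, fit_test: HillFit, alpha: float = 0.05
) -> StoichiometryReport:
    """Classify binding-site stoichiometry from a reference and a one-site-dead fit.

    For a dimeric channel with two equivalent activator sites, knocking out
    one site halves E_max with unchanged EC50 if site occupancy contributes
    proportionally to the effect (``proportional-occupancy``), whereas an
    unchanged E_max indicates that occupying a single site already elicits
    the full response (``single-site-sufficient``).  Decisions use z-tests on
    the ratios at the given alpha.
    """
    if not (fit_ref.converged and fit_test.converged):
        raise ValueError("both fits must have converged")
    emr, emr_se = _ratio_with_se(
        fit_test.e_max, fit_test.se_e_max, fit_ref.e_max, fit_ref.se_e_max
    )
    ecr, ecr_se = _ratio_with_se(
        fit_test.ec50, fit_test.se_ec50, fit_ref.ec50, fit_ref.se_ec50
    )
    p_one = _z_p(emr, 1.0, emr_se)
    p_half = _z_p(emr, 0.5, emr_se)
    p_ec = _z_p(ecr, 1.0, ecr_se)
    if p_one > alpha:
        cls = "single-site-sufficient"
    elif p_half > alpha and p_ec > alpha:
        cls = "proportional-occupancy"
    else:
        cls = "indeterminate"
    return StoichiometryReport(
        e_max_ratio=emr,
        e_max_ratio_se=emr_se,
        ec50_ratio=ecr,
        ec50_ratio_se=ecr_se,
        p_e_max_vs_one=p_one,
        p_e_max_vs_half=p_half,
        p_ec50_vs_one=p_ec,
        classification=cls,
    )


@dataclass(frozen=True)
class AntagonismReport:
    classification: str  # competitive / noncompetitive / indeterminate
    e_max_trend_significant: bool
    ec50_trend_significant: bool
    kb_noncompetitive_uM: float | None
    kb_competitive_uM: float | None
    table: pd.DataFrame  # antagonist_uM, e_max, ec50 (+ SEs)


def classify_antagonism(
    fits: Sequence[HillFit],
    antagonist_concs: Sequence[float],
    alpha: float = 0.05,
) -> AntagonismReport:
    """Distinguish competitive from noncompetitive (allosteric) antagonism.

    Across increasing antagonist levels (the first must be zero), a
    significant monotone *decrease of E_max with preserved EC50* is the
    allosteric signature, while a significant monotone *increase of EC50
    with preserved E_max* is the competitive (Gaddum) signature.  Each
    nonzero level is z-tested against the zero-antagonist fit.  The apparent
    parameters are additionally fitted to ``E_max / (1 + [B]/Kb)`` and
    ``EC50 * (1 + [B]/Kb)`` to estimate Kb under either mechanism.
    """
    concs = [float(b) for b in antagonist_concs]
    if len(fits) != len(concs) or len(concs) < 3:
        raise ValueError("need >= 3 antagonist levels with matching fits")
    if concs[0] != 0.0 or sorted(concs) != concs:
        raise ValueError("antagonist levels must start at 0 and increase")
    if not all(f.converged for f in fits):
        raise ValueError("all fits must have converged")

    base = fits[0]
    emax = np.array([f.e_max for f in fits])
    ec50 = np.array([f.ec50 for f in fits])
    em_down = all(
        _z_p(f.e_max, base.e_max, _pooled_se(f.se_e_max, base.se_e_max)) < alpha
        and f.e_max < base.e_max
        for f in fits[1:]
    ) and np.all(np.diff(emax) < 0)
    ec_up = all(
        _z_p(f.ec50, base.ec50, _pooled_se(f.se_ec50, base.se_ec50)) < alpha
        and f.ec50 > base.ec50
        for f in fits[1:]
    ) and np.all(np.diff(ec50) > 0)

    if em_down and not ec_up:
        cls = "noncompetitive"
    elif ec_up and not em_down:
        cls = "competitive"
    else:
        cls = "indeterminate"

    b = np.array(concs)

    def _fit_kb(observed: np.ndarray, model) -> float | None:
        from scipy.optimize import least_squares

        try:
            res = least_squares(
                lambda kb: model(b, kb[0]) - observed, x0=[max(b[1], 1.0)],
                bounds=([1e-9], [np.inf]),
            )
            return float(res.x[0])
        except Exception:
            return None

    kb_nc = _fit_kb(emax, lambda bb, kb: base.e_max / (1.0 + bb / kb))
    kb_c = _fit_kb(ec50, lambda bb, kb: base.ec50 * (1.0 + bb / kb))
    table = pd.DataFrame(
        {
            "antagonist_uM": concs,
            "e_max": emax,
            "se_e_max": [f.se_e_max for f in fits],
            "ec50": ec50,
            "se_ec50": [f.se_ec50 for f in fits],
        }
    )
    return AntagonismReport(
        classification=cls,
        e_max_trend_significant=bool(em_down),
        ec50_trend_significant=bool(ec_up),
        kb_noncompetitive_uM=kb_nc,
        kb_competitive_uM=kb_c,
        table=table,
    )


def _pooled_se(se_a: float | None, se_b: float | None) -> float:
    a = 0.0 if se_a is None else se_a
    b = 0.0 if se_b is None else se_b
    return math.sqrt(a * a + b * b)


# ----------------------------------------------------------------------------
# selectivity-filter inactivation kinetics


def compute_FI(i_tail: float, i_steady: float) -> float:
    """Fraction of partially inactivated channels, ``(1 - I_steady/I_tail) * 100``.

    The tail current is taken immediately after the hyperpolarizing step,
    before inactivation develops; the steady-state current at the end of the
    same pulse.  Negative values (facilitation) are permitted but flagged.
    """
    if i_tail == 0:
        raise ValueError("zero tail current")
    if i_steady != 0 and (i_steady > 0) != (i_tail > 0):
        raise ValueError("current sign mismatch between tail and steady state")
    fi = (1.0 - i_steady / i_tail) * 100.0
    if fi < 0:
        warnings.warn(f"negative inactivated fraction {fi:.3g}% (facilitation)", stacklevel=2)
    return fi


def _growth(x, a, b, c):
    return a - b * c**x


@dataclass(frozen=True)
class GrowthFit:
    a: float  # steady-state F_I (%)
    b: float  # accessible range (%)
    c: float  # per-ms retention factor, 0 < c < 1
    se_a: float | None
    se_b: float | None
    se_c: float | None
    residual_ss: float
    converged: bool

    def predict(self, x):
        return _growth(np.asarray(x, dtype=float), self.a, self.b, self.c)


def fit_inactivation_growth(
    durations_ms: Sequence[float], fi_pct: Sequence[float]
) -> GrowthFit:
    """Fit ``F_I = a - b * c^x`` against the depolarizing inter-pulse duration.

    The constraint 0 < c < 1 makes the curve an asymptotic growth toward the
    steady-state fraction ``a``.  Initialization scans a grid of retention
    factors with the amplitudes solved linearly, then polishes with
    constrained least squares.
    """
    x = np.asarray(durations_ms, dtype=float)
    y = np.asarray(fi_pct, dtype=float)
    if np.unique(x).size < 4:
        raise ValueError("at least 4 inter-pulse durations required")

    best = None
    for c0 in np.exp(-1.0 / np.geomspace(2.0, 2000.0, 25)):
        basis = np.column_stack([np.ones_like(x), -(c0**x)])
        coef, res, *_ = np.linalg.lstsq(basis, y, rcond=None)
        ss = float(np.sum((basis @ coef - y) ** 2))
        if best is None or ss < best[0]:
            best = (ss, coef[0], coef[1], c0)
    _, a0, b0, c0 = best

    model = Model(_growth)
    params = Parameters()
    params.add("a", value=float(a0))
    params.add("b", value=float(b0))
    params.add("c", value=float(np.clip(c0, 1e-9, 1 - 1e-12)), min=1e-12, max=1 - 1e-12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(y, params, x=x)
    p = result.params
    return GrowthFit(
        a=float(p["a"].value),
        b=float(p["b"].value),
        c=float(p["c"].value),
        se_a=None if p["a"].stderr is None else float(p["a"].stderr),
        se_b=None if p["b"].stderr is None else float(p["b"].stderr),
        se_c=None if p["c"].stderr is None else float(p["c"].stderr),
        residual_ss=float(np.sum(result.residual**2)),
        converged=bool(result.success),
    )


def _single_exp(x, a0, a1, tau):
    return a0 + a1 * np.exp(-x / tau)


@dataclass(frozen=True)
class ExponentialFit:
    a0: float  # steady-state level
    a1: float  # amplitude
    tau: float  # time constant, same unit as x
    se_a0: float | None
    se_a1: float | None
    se_tau: float | None
    residual_ss: float
    converged: bool
    identifiable: bool  # False for flat traces where tau is meaningless

    def predict(self, x):
        return _single_exp(np.asarray(x, dtype=float), self.a0, self.a1, self.tau)


def fit_exponential_tau(
    x: Sequence[float], y: Sequence[float], *, flat_rel_tol: float = 1e-3
) -> ExponentialFit:
    """Fit a single-exponential relaxation ``y = a0 + a1 * exp(-x/tau)``.

    A single component suffices when the underlying process is one
    transition between two states.  Initialization: a0 from the final value,
    a1 from the initial-minus-final difference, tau at a fifth of the span.
    Flat traces (amplitude indistinguishable from zero) are flagged as
    non-identifiable rather than reported with a spurious tau.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("segment must contain at least 10 samples")
    span = float(x.max() - x.min())
    if span <= 0:
        raise ValueError("degenerate x range")
    scale = max(float(np.max(np.abs(y))), 1e-12)
    model = Model(_single_exp)
    params = Parameters()
    params.add("a0", value=float(y[-1]))
    params.add("a1", value=float(y[0] - y[-1]))
    params.add("tau", value=span / 5.0, min=1e-9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(y, params, x=x - x.min())
    p = result.params
    a1 = float(p["a1"].value)
    se_tau = None if p["tau"].stderr is None else float(p["tau"].stderr)
    tau = float(p["tau"].value)
    identifiable = abs(a1) > flat_rel_tol * scale and not (
        se_tau is not None and se_tau > 10.0 * tau
    )
    return ExponentialFit(
        a0=float(p["a0"].value),
        a1=a1,
        tau=tau,
        se_a0=None if p["a0"].stderr is None else float(p["a0"].stderr),
        se_a1=None if p["a1"].stderr is None else float(p["a1"].stderr),
        se_tau=se_tau,
        residual_ss=float(np.sum(result.residual**2)),
        converged=bool(result.success),
        identifiable=bool(identifiable),
    )


# ----------------------------------------------------------------------------
# group statistics


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class StatsReport:
    anova_F: float | None
    anova_p: float | None
    anova_df: tuple[int, int] | None
    tukey: pd.DataFrame | None  # group_a, group_b, p_adj, stars
    t_stat: float | None
    t_p: float | None
    t_df: int | None
    sem: Mapping[str, float] = field(default_factory=dict)


def group_stats(groups: Mapping[str, Sequence[float]]) -> StatsReport:
    """One-way ANOVA with Tukey HSD, plus a two-sided t-test for two groups.

    The t-test uses the pooled-variance (equal-variance) form.  SEM is
    reported per group with the n-1 denominator.  Adjusted Tukey p-values
    carry the conventional significance stars (ns / * / ** / ***).
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    sem = {k: float(sps.sem(a, ddof=1)) for k, a in zip(names, arrays)}

    F, p = sps.f_oneway(*arrays)
    df1 = len(arrays) - 1
    df2 = sum(a.size for a in arrays) - len(arrays)

    hsd = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            padj = float(hsd.pvalue[i, j])
            rows.append((names[i], names[j], padj, significance_stars(padj)))
    tukey = pd.DataFrame(rows, columns=["group_a", "group_b", "p_adj", "stars"])

    t_stat = t_p = t_df = None
    if len(arrays) == 2:
        t = sps.ttest_ind(arrays[0], arrays[1], equal_var=True)
        t_stat, t_p = float(t.statistic), float(t.pvalue)
        t_df = arrays[0].size + arrays[1].size - 2

    return StatsReport(
        anova_F=float(F),
        anova_p=float(p),
        anova_df=(df1, df2),
        tukey=tukey,
        t_stat=t_stat,
        t_p=t_p,
        t_df=t_df,
        sem=sem,
    )
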