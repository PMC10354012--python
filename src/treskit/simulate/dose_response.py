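"""Generators for Hill-shaped dose-response data under four receptor models.

``single_site_hill``
    activity = E_max * c^h / (c^h + EC50^h)
``two_site_proportional``
    Two identical Langmuir sites, each contributing half of E_max when
    functional: activity = n_functional * (E_max / 2) * c / (c + Kd).
    Knocking out one of the two sites therefore halves the fitted E_max
    while leaving the apparent EC50 (= Kd) untouched.
``competitive_antagonist``
    Gaddum shift: apparent EC50 = EC50 * (1 + [B]/Kb), E_max preserved.
``noncompetitive_antagonist``
    Allosteric depression: apparent E_max = E_max / (1 + [B]/Kb), EC50
    preserved.

Activities are in percent (the relative current-increase scale); replicate
noise is additive Gaussian, seeded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["DoseResponseModelSpec", "predict_activity", "simulate_dose_response"]

MODEL_KINDS = (
    "single_site_hill",
    "two_site_proportional",
    "competitive_antagonist",
    "noncompetitive_antagonist",
)


@dataclass(frozen=True)
class DoseResponseModelSpec:
    model_kind: str = "single_site_hill"
    e_max: float = 360.0  # % activity at saturation
    ec50: float = 64.0  # uM; per-site Kd for the two-site model
    hill: float = 1.0
    functional_sites: int = 2
    antagonist_conc: float = 0.0  # uM
    antagonist_kb: float = 1.0  # uM
    replicate_noise_sd: float = 0.0  # % activity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if self.ec50 <= 0 or self.antagonist_kb <= 0:
            raise ValueError("EC50/Kd and Kb must be positive")
        if self.e_max < 0 or self.hill <= 0:
            raise ValueError("E_max must be >= 0 and h > 0")
        if self.functional_sites not in (1, 2):
            raise ValueError("functional_sites must be 1 or 2")
        if self.antagonist_conc < 0 or self.replicate_noise_sd < 0:
            raise ValueError("antagonist_conc and noise must be >= 0")


def predict_activity(
    spec: DoseResponseModelSpec, concentrations: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Noise-free activity (%) at the given agonist concentrations (uM)."""
    c = np.asarray(concentrations, dtype=float)
    if c.size == 0:
        raise ValueError("empty concentration list")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    kind = spec.model_kind
    if kind == "single_site_hill":
        return spec.e_max * c**spec.hill / (c**spec.hill + spec.ec50**spec.hill)
    if kind == "two_site_proportional":
        return spec.functional_sites * (spec.e_max / 2.0) * c / (c + spec.ec50)
    shift = 1.0 + spec.antagonist_conc / spec.antagonist_kb
    if kind == "competitive_antagonist":
        ec50_app = spec.ec50 * shift
        return spec.e_max * c**spec.hill / (c**spec.hill + ec50_app**spec.hill)
    # noncompetitive
    e_max_app = spec.e_max / shift
    return e_max_app * c**spec.hill / (c**spec.hill + spec.ec50**spec.hill)


def simulate_dose_response(
    spec: DoseResponseModelSpec,
    concentrations: Sequence[float],
    n_replicates: int = 1,
    *,
    construct: str = "WT",
) -> pd.DataFrame:
    """Seeded replicate activities; columns construct, replicate, conc_uM, activity_pct."""
    mean = predict_activity(spec, concentrations)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for r in range(n_replicates):
        noise = (
            rng.normal(0.0, spec.replicate_noise_sd, size=mean.size)
            if spec.replicate_noise_sd > 0
            else np.zeros_like(mean)
        )
        for c, a in zip(concentrations, mean + noise):
            rows.append((construct, r, float(c), float(a)))
    return pd.DataFrame(rows, columns=["construct", "replicate", "conc_uM", "activity_pct"])
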