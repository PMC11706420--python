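"""System (drug-independent) physiology and Monte-Carlo virtual populations.

The defaults describe a healthy adult: organ masses and blood flows at
conventional reference values, and liver/kidney protein and cellularity
scalars with their reported inter-individual coefficients of variation.
Aldehyde oxidase is treated as a cytosolic enzyme expressed in liver and
kidney, with kidney abundance 10% of liver on a per-mg-cytosolic-protein
basis and no other extrahepatic expression.

Virtual subjects are drawn by sampling every CV-bearing scalar
independently from a lognormal distribution parameterized by its
arithmetic mean ``m`` and coefficient of variation ``cv``
(``sigma^2 = ln(1 + cv^2)``, ``mu = ln m - sigma^2/2``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: enzyme degradation rate constant used for time-dependent inhibition,
#: 1/min (average of reported P450 turnover values; no AO-specific value
#: has been measured)
KDEG_DEFAULT_PER_MIN = 0.00026


@dataclass(frozen=True)
class SystemPhysiology:
    """Whole-body system parameters; masses g, flows L/h, proteins mg/g."""

    body_weight: float = 70.0  # kg
    liver_mass: float = 1650.0  # g
    hepatic_blood_flow: float = 97.0  # L/h
    kidney_mass: float = 310.0  # g (both kidneys)
    cortex_fraction: float = 0.70
    renal_blood_flow: float = 66.0  # L/h
    hpgl: float = 120.0  # 1e6 hepatocytes / g liver
    hpgl_cv: float = 42.0  # %
    cppgl: float = 80.7  # mg cytosolic protein / g liver
    cppgl_cv: float = 30.0
    mppgl: float = 40.0  # mg microsomal protein / g liver
    mppgl_cv: float = 27.0
    cppgk: float = 53.3  # mg cytosolic protein / g kidney cortex
    cppgk_cv: float = 30.0
    mppgk: float = 26.2  # mg microsomal protein / g kidney cortex
    mppgk_cv: float = 30.0
    ao_liver_cv: float = 37.0  # % CV in hepatic AO abundance
    ao_kidney_cv: float = 52.0  # % CV in renal AO abundance
    ao_kidney_rel_abundance: float = 0.10  # kidney:liver AO per mg cytosolic protein
    gut_to_liver_cyp3a4_ratio: float = 0.01
    villous_blood_flow: float = 18.0  # L/h
    kdeg_enzyme: float = KDEG_DEFAULT_PER_MIN  # 1/min

    def __post_init__(self):
        for name in (
            "body_weight",
            "liver_mass",
            "hepatic_blood_flow",
            "kidney_mass",
            "renal_blood_flow",
            "hpgl",
            "cppgl",
            "mppgl",
            "cppgk",
            "mppgk",
            "villous_blood_flow",
            "kdeg_enzyme",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hpgl_cv", "cppgl_cv", "mppgl_cv", "cppgk_cv", "mppgk_cv",
                     "ao_liver_cv", "ao_kidney_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.cortex_fraction <= 1.0:
            raise ValueError("cortex_fraction must be in [0,1]")
        if not 0.0 <= self.ao_kidney_rel_abundance <= 1.0:
            raise ValueError("ao_kidney_rel_abundance must be in [0,1]")

    @property
    def kidney_cortex_mass(self) -> float:
        return self.kidney_mass * self.cortex_fraction

    def replace(self, **changes) -> "SystemPhysiology":
        return replace(self, **changes)


def default_physiology() -> SystemPhysiology:
    """The packaged healthy-adult default physiology."""
    return SystemPhysiology()


#: scalars that carry a CV and are drawn per subject; maps the sampled
#: column name to (mean attribute, cv attribute)
_SAMPLED = {
    "hpgl": ("hpgl", "hpgl_cv"),
    "cppgl": ("cppgl", "cppgl_cv"),
    "mppgl": ("mppgl", "mppgl_cv"),
    "cppgk": ("cppgk", "cppgk_cv"),
    "mppgk": ("mppgk", "mppgk_cv"),
    "ao_liver_activity": (None, "ao_liver_cv"),  # multiplicative, mean 1
    "ao_kidney_activity": (None, "ao_kidney_cv"),
}


def lognormal_sigma(cv_percent: float) -> float:
    """Lognormal shape parameter for a given arithmetic CV (%)."""
    cv = cv_percent / 100.0
    return math.sqrt(math.log1p(cv * cv))


@dataclass(frozen=True)
class PopulationSample:
    """Per-subject draws of the CV-bearing physiological scalars."""

    physiology: SystemPhysiology
    seed: int
    draws: pd.DataFrame = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.draws)

    def summary(self) -> dict[str, float]:
        return self.draws.mean().to_dict()


def sample_population(
    phys: SystemPhysiology, n: int, seed: int
) -> PopulationSample:
    """Draw ``n`` virtual subjects; reproducible for fixed ``(n, seed)``.

    Each scalar is sampled independently lognormally with the stated
    arithmetic mean and CV; AO activity enters as a multiplicative
    factor with mean 1.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    cols = {}
    for col, (mean_attr, cv_attr) in _SAMPLED.items():
        mean = 1.0 if mean_attr is None else getattr(phys, mean_attr)
        sigma = lognormal_sigma(getattr(phys, cv_attr))
        if sigma == 0.0:
            cols[col] = np.full(n, mean)
        else:
            mu = math.log(mean) - 0.5 * sigma * sigma
            cols[col] = rng.lognormal(mu, sigma, size=n)
    draws = pd.DataFrame(cols, index=pd.RangeIndex(n, name="subject"))
    return PopulationSample(physiology=phys, seed=seed, draws=draws)


def summarize_scalars(sample: PopulationSample) -> SystemPhysiology:
    """Mean-subject physiology: arithmetic mean of every sampled scalar,
    other parameters unchanged.  This is the deterministic physiology used
    for retrograde (middle-out/top-down) calculations."""
    if sample.n == 0:
        raise ValueError("empty population sample")
    means = sample.summary()
    updates = {
        mean_attr: means[col]
        for col, (mean_attr, _) in _SAMPLED.items()
        if mean_attr is not None
    }
    return sample.physiology.replace(**updates)
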