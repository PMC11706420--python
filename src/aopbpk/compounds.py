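"""Drug parameter records for AO / dual AO-CYP3A4 PBPK modelling.

A :class:`CompoundRecord` collects everything a whole-body model needs for
one drug: physicochemistry, plasma and incubational binding, in vitro
intrinsic clearances per system (liver microsomes, liver cytosol, or
hepatocytes) and pathway (AO vs non-AO), absorption and distribution
parameters, and the observed systemic/renal clearances used for model
refinement and evaluation.

Unit conventions
----------------
Assay-scale quantities keep their bench units (apparent CLint in
uL/min/mg protein or uL/min/1e6 cells, permeability in 1e-6 cm/s,
blood-to-plasma query concentrations in ng/mL).  Everything at the
whole-body scale is litres, hours and milligrams; conversion from assay
units happens once, inside the organ scaling step of :mod:`aopbpk.ivive`.

Six drug records (capmatinib, idelalisib, lenvatinib, zaleplon,
ziprasidone, zoniporide) ship with the package as YAML documents under
``aopbpk/data``.
"""

from __future__ import annotations

import enum
import math
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, NonNegativeFloat, field_validator, model_validator


class InVitroSystem(str, enum.Enum):
    HLC = "HLC"  # human liver cytosol, uL/min/mg cytosolic protein
    HLM = "HLM"  # human liver microsomes, uL/min/mg microsomal protein
    HH = "HH"  # human hepatocytes, uL/min/1e6 cells


class Pathway(str, enum.Enum):
    AO = "AO"
    NON_AO = "nonAO"  # treated as CYP3A4 for dual AO-CYP3A4 substrates
    TOTAL = "total"


class IonizationClass(str, enum.Enum):
    NEUTRAL = "neutral"
    BASE = "base"
    AMPHOLYTE = "ampholyte"
    DIPROTIC_BASE = "diprotic base"


class ConfigurationError(ValueError):
    """A record is internally inconsistent or incomplete for the requested use."""


class InVitroClintEntry(BaseModel):
    """One substrate-depletion measurement of apparent intrinsic clearance.

    ``value`` is the apparent (binding-uncorrected) CLint in uL/min/mg
    protein for HLC/HLM or uL/min/1e6 cells for HH; ``fu_inc`` is the
    unbound fraction in the incubation used to correct it.
    """

    system: InVitroSystem
    pathway: Pathway
    value: NonNegativeFloat
    fu_inc: float = Field(gt=0.0, le=1.0)
    protein_conc: Optional[float] = Field(default=None, gt=0.0)

    @property
    def unbound_value(self) -> float:
        """Binding-corrected apparent CLint (same assay units as ``value``)."""
        return self.value / self.fu_inc


class BloodPlasmaRatio(BaseModel):
    """Blood-to-plasma concentration ratio, possibly concentration dependent.

    ``points`` maps plasma concentration (ng/mL; ``None`` = any
    concentration, for single-point data) to the measured ratio.
    """

    points: list[tuple[Optional[float], float]] = Field(min_length=1)

    @field_validator("points")
    @classmethod
    def _check_points(cls, pts):
        for conc, ratio in pts:
            if ratio <= 0:
                raise ValueError(f"B/P ratio must be positive, got {ratio}")
            if conc is not None and conc <= 0:
                raise ValueError(f"B/P tabulated concentration must be positive, got {conc}")
        return pts

    def at(self, plasma_conc: Optional[float] = None) -> float:
        """Ratio at the tabulated concentration nearest ``plasma_conc``.

        Nearest is judged on the log-concentration scale, which makes the
        lookup invariant to the concentration unit.  Single-point tables
        (or ``plasma_conc=None``) return the sole/first ratio.
        """
        if not self.points:
            raise ConfigurationError("empty B/P table")
        concless = [r for c, r in self.points if c is None]
        if concless and len(self.points) == len(concless):
            return concless[0]
        if plasma_conc is None:
            if len(self.points) == 1:
                return self.points[0][1]
            raise ConfigurationError(
                "B/P table is concentration dependent; a query concentration is required"
            )
        if plasma_conc <= 0:
            raise ValueError("plasma concentration must be positive")
        tabulated = [(c, r) for c, r in self.points if c is not None]
        if not tabulated:
            return self.points[0][1]
        return min(tabulated, key=lambda cr: abs(math.log(plasma_conc / cr[0])))[1]


class Distribution(BaseModel):
    """Distribution block: minimal PBPK (Vss + single adjusting compartment)
    or full PBPK with an externally supplied Kp set."""

    model: str = Field(pattern="^(minimal|full)$")
    vss: NonNegativeFloat  # L/kg
    vsac: NonNegativeFloat = 0.0  # L/kg
    q_intercompartment: NonNegativeFloat = 0.0  # L/h
    kp_scalar: float = Field(default=1.0, gt=0.0)
    kp_set: Optional[dict[str, float]] = None

    @model_validator(mode="after")
    def _vss_ge_vsac(self):
        if self.vss < self.vsac:
            raise ValueError(f"Vss ({self.vss}) must be >= Vsac ({self.vsac})")
        return self


class ObservedClearance(BaseModel):
    """Observed plasma clearance (L/h), optionally sex-stratified.

    The scalar summary of stratified data is the unweighted geometric
    mean of the strata.
    """

    route: str = Field(pattern="^(iv|oral)$")
    value: Optional[NonNegativeFloat] = None
    cv_percent: Optional[NonNegativeFloat] = None
    strata: Optional[dict[str, float]] = None

    @model_validator(mode="after")
    def _has_value(self):
        if self.value is None and not self.strata:
            raise ValueError("observed clearance needs a value or strata")
        return self

    @property
    def summary(self) -> float:
        if self.strata:
            vals = list(self.strata.values())
            return math.exp(sum(math.log(v) for v in vals) / len(vals))
        return float(self.value)


class FmObserved(BaseModel):
    """Observed pathway fractions (e.g. from a human mass-balance study)
    with optional min/max uncertainty bounds."""

    mean: Optional[dict[str, float]] = None
    minimum: Optional[dict[str, float]] = None
    maximum: Optional[dict[str, float]] = None

    @model_validator(mode="after")
    def _check(self):
        if self.mean is None and self.minimum is None and self.maximum is None:
            raise ValueError("fm_obs needs at least one of mean/minimum/maximum")
        for tbl in (self.mean, self.minimum, self.maximum):
            if tbl is None:
                continue
            for k, v in tbl.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"fm[{k}]={v} outside [0,1]")
        if self.minimum and self.maximum:
            for k in self.minimum:
                if k in self.maximum and self.minimum[k] > self.maximum[k]:
                    raise ValueError(f"fm[{k}] min > max")
        return self


class DoseRegimen(BaseModel):
    """Dosing regimen: single or repeated iv bolus / iv infusion / oral doses."""

    route: str = Field(pattern="^(iv-bolus|iv-infusion|oral)$")
    dose: float = Field(gt=0.0)  # mg
    infusion_duration: Optional[float] = Field(default=None, gt=0.0)  # h
    n_doses: int = Field(default=1, ge=1)
    interval: Optional[float] = Field(default=None, gt=0.0)  # h

    @model_validator(mode="after")
    def _check(self):
        if self.route == "iv-infusion" and self.infusion_duration is None:
            raise ValueError("iv-infusion requires infusion_duration")
        if self.n_doses > 1 and self.interval is None:
            raise ValueError("multiple doses require a dosing interval")
        return self


class CompoundRecord(BaseModel):
    """Complete drug-specific parameter set for PBPK model construction."""

    name: str
    mw: float = Field(gt=0.0)  # g/mol
    ionization: IonizationClass
    logp: float
    pka1: Optional[float] = None
    pka2: Optional[float] = None
    fu_p: float = Field(gt=0.0, le=1.0)
    bp: BloodPlasmaRatio
    papp: Optional[float] = Field(default=None, gt=0.0)  # 1e-6 cm/s
    fa: Optional[float] = Field(default=None, gt=0.0, le=1.0)
    ka: Optional[float] = Field(default=None, gt=0.0)  # 1/h
    t_lag: NonNegativeFloat = 0.0  # h
    fu_gut: Optional[float] = Field(default=None, gt=0.0, le=1.0)
    qgut: Optional[float] = Field(default=None, gt=0.0)  # L/h
    distribution: Distribution
    clint_entries: list[InVitroClintEntry] = Field(default_factory=list)
    cl_obs: Optional[ObservedClearance] = None
    cl_renal_obs: NonNegativeFloat = 0.0  # L/h, plasma
    cl_biliary: NonNegativeFloat = 0.0  # L/h, plasma
    fm_obs: Optional[FmObserved] = None
    regimen: Optional[DoseRegimen] = None

    @model_validator(mode="after")
    def _no_total_with_split(self):
        for system in InVitroSystem:
            entries = [e for e in self.clint_entries if e.system == system]
            has_total = any(e.pathway == Pathway.TOTAL for e in entries)
            has_split = any(e.pathway != Pathway.TOTAL for e in entries)
            if has_total and has_split:
                raise ValueError(
                    f"{system.value}: 'total' entry cannot coexist with AO/nonAO entries"
                )
        return self

    def entry(self, system: InVitroSystem | str, pathway: Pathway | str) -> InVitroClintEntry:
        system, pathway = InVitroSystem(system), Pathway(pathway)
        for e in self.clint_entries:
            if e.system == system and e.pathway == pathway:
                return e
        raise ConfigurationError(f"{self.name}: no {system.value}/{pathway.value} CLint entry")

    def has_entry(self, system: InVitroSystem | str, pathway: Pathway | str) -> bool:
        try:
            self.entry(system, pathway)
            return True
        except ConfigurationError:
            return False

    @property
    def effective_fu_gut(self) -> float:
        """fu_gut, defaulting to fu_p when not measured."""
        return self.fu_gut if self.fu_gut is not None else self.fu_p


# ---------------------------------------------------------------------------
# serialization


def load_compound(source) -> CompoundRecord:
    """Load and validate a compound record from a mapping, YAML text or path.

    Raises a pydantic :class:`~pydantic.ValidationError` naming the
    offending field for missing or out-of-range values.
    """
    if isinstance(source, CompoundRecord):
        return source
    if isinstance(source, dict):
        return CompoundRecord.model_validate(source)
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    return CompoundRecord.model_validate(yaml.safe_load(text))


def dump_compound(compound: CompoundRecord) -> str:
    """Serialize a record to YAML such that :func:`load_compound` round-trips."""
    return yaml.safe_dump(
        compound.model_dump(mode="json", exclude_none=True), sort_keys=False
    )


FIXTURE_NAMES = (
    "capmatinib",
    "idelalisib",
    "lenvatinib",
    "zaleplon",
    "ziprasidone",
    "zoniporide",
)


def fixture(name: str) -> CompoundRecord:
    """Load one of the six packaged drug records."""
    name = name.lower()
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    text = resources.files("aopbpk.data").joinpath(f"{name}.yaml").read_text()
    return load_compound(text)


def all_fixtures() -> dict[str, CompoundRecord]:
    return {n: fixture(n) for n in FIXTURE_NAMES}


# ---------------------------------------------------------------------------
# small predictive helpers


def select_bp(compound: CompoundRecord, plasma_conc: Optional[float] = None) -> float:
    """Blood-to-plasma ratio at the tabulated point nearest ``plasma_conc``
    (ng/mL) on the log-concentration scale."""
    return compound.bp.at(plasma_conc)


#: Regression of human jejunal effective permeability on MDCK apparent
#: permeability: logPeff = 0.6431*logPapp - 0.34 (Peff in 1e-4 cm/s,
#: Papp in 1e-6 cm/s).
PEFF_SLOPE = 0.6431
PEFF_INTERCEPT = -0.34


def predict_peff(papp: float) -> float:
    """Effective jejunal permeability (1e-4 cm/s) from apparent
    permeability (1e-6 cm/s)."""
    if papp <= 0:
        raise ValueError(f"papp must be positive, got {papp}")
    return 10.0 ** (math.log10(papp) * PEFF_SLOPE + PEFF_INTERCEPT)
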