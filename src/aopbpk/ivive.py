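"""In vitro - in vivo extrapolation of intrinsic clearance.

Apparent intrinsic clearances measured in human liver cytosol (HLC),
human liver microsomes (HLM) or human hepatocytes (HH) are corrected for
incubational binding, multiplied by system-specific empirical scaling
factors (ESFs), and scaled to whole-organ unbound intrinsic clearance
with protein/cellularity scalars and organ mass.  Cytosolic activity is
attributed to aldehyde oxidase (AO) and microsomal activity to CYP3A4;
hepatocyte assays are split into AO and non-AO by chemical AO inhibition.

AO is also expressed in kidney cortex at 10% of the hepatic abundance
per mg cytosolic protein, so every AO liver pathway is accompanied by a
(small) kidney AO pathway.

The container produced here, :class:`PathwayClearances`, carries the
per-organ intrinsic clearances, the systemic blood/plasma clearances
derived from them by the organ models of :mod:`aopbpk.clearance`, and
the fraction-metabolized (fm) table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .compounds import (
    CompoundRecord,
    ConfigurationError,
    InVitroClintEntry,
    InVitroSystem,
    Pathway,
)
from .physiology import SystemPhysiology

#: canonical pathway labels used throughout the package
PATH_AO = "AO"
PATH_CYP3A4 = "CYP3A4"
PATH_RENAL = "renal_excretion"
PATH_BILIARY = "biliary"
METABOLIC_PATHWAYS = (PATH_AO, PATH_CYP3A4)

#: uL/min -> L/h
UL_PER_MIN_TO_L_PER_H = 60e-6

FM_TOL = 1e-9


@dataclass(frozen=True)
class ESFPolicy:
    """Empirical scaling factors correcting systematic IVIVE underprediction.

    Factors are system- and pathway-specific: cytosol-AO 5.6,
    microsomes-CYP 2.8, hepatocytes-AO 10.4, hepatocytes-non-AO 4.2.
    A disabled policy behaves as all-ones (physiological scaling only).
    """

    hlc_ao: float = 5.6
    hlm_nonao: float = 2.8
    hh_ao: float = 10.4
    hh_nonao: float = 4.2
    enabled: bool = True

    def __post_init__(self):
        for name in ("hlc_ao", "hlm_nonao", "hh_ao", "hh_nonao"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def factor(self, system: InVitroSystem | str, pathway: Pathway | str) -> float:
        if not self.enabled:
            return 1.0
        system, pathway = InVitroSystem(system), Pathway(pathway)
        if system is InVitroSystem.HLC:
            return self.hlc_ao
        if system is InVitroSystem.HLM:
            return self.hlm_nonao
        return self.hh_ao if pathway is Pathway.AO else self.hh_nonao

    @classmethod
    def disabled(cls) -> "ESFPolicy":
        return cls(enabled=False)


def transpose_binding(fu_ref: float, c_ref: float, c_target: float) -> float:
    """Transpose an incubational unbound fraction between protein
    concentrations assuming a single nonspecific binding class
    (Hallifax-Houston style).

    ``Ka = (1/fu_ref - 1)/c_ref``; returns ``1/(1 + Ka*c_target)``.
    """
    if not 0.0 < fu_ref <= 1.0:
        raise ValueError(f"fu_ref must be in (0,1], got {fu_ref}")
    if c_ref <= 0 or c_target <= 0:
        raise ValueError("protein concentrations must be positive")
    ka = (1.0 / fu_ref - 1.0) / c_ref
    return 1.0 / (1.0 + ka * c_target)


def _per_mg_cytosolic(entry: InVitroClintEntry, phys: SystemPhysiology, esf: ESFPolicy) -> float:
    """Unbound, ESF-scaled CLint per mg cytosolic protein (uL/min/mg),
    the common currency for kidney AO scaling."""
    scaled = entry.unbound_value * esf.factor(entry.system, entry.pathway)
    if entry.system is InVitroSystem.HLC:
        return scaled
    if entry.system is InVitroSystem.HH:
        # per-1e6-cells -> per-mg-cytosolic via hepatocellularity / cytosolic
        # protein content of liver
        return scaled * phys.hpgl / phys.cppgl
    raise ConfigurationError(
        "kidney AO scaling needs a cytosolic-equivalent input (HLC or HH), "
        f"got {entry.system.value}"
    )


def scale_clint_organ(
    entry: InVitroClintEntry,
    organ: str,
    phys: SystemPhysiology,
    esf: ESFPolicy,
) -> float:
    """Whole-organ unbound intrinsic clearance (L/h) from one assay entry.

    Liver scaling uses the protein/cellularity scalar matching the assay
    system (CPPGL for cytosol, MPPGL for microsomes, HPGL for
    hepatocytes) and liver mass.  Kidney scaling applies only to the AO
    pathway: the cytosolic-equivalent per-mg value is multiplied by the
    kidney:liver relative AO abundance, kidney-cortex cytosolic protein
    content and cortex mass.
    """
    if organ == "liver":
        scalar = {
            InVitroSystem.HLC: phys.cppgl,
            InVitroSystem.HLM: phys.mppgl,
            InVitroSystem.HH: phys.hpgl,
        }[entry.system]
        scaled = entry.unbound_value * esf.factor(entry.system, entry.pathway)
        return scaled * scalar * phys.liver_mass * UL_PER_MIN_TO_L_PER_H
    if organ == "kidney":
        if entry.pathway is not Pathway.AO:
            raise ConfigurationError("kidney metabolic scaling is AO-only")
        per_mg = _per_mg_cytosolic(entry, phys, esf)
        return (
            per_mg
            * phys.ao_kidney_rel_abundance
            * phys.cppgk
            * phys.kidney_cortex_mass
            * UL_PER_MIN_TO_L_PER_H
        )
    raise ConfigurationError(f"unknown organ {organ!r}")


def kidney_to_liver_ao_ratio(phys: SystemPhysiology) -> float:
    """Ratio of kidney-AO to liver-AO whole-organ CLint,u for any
    cytosol-sourced AO pathway (compound independent)."""
    return (
        phys.ao_kidney_rel_abundance
        * phys.cppgk
        * phys.kidney_cortex_mass
        / (phys.cppgl * phys.liver_mass)
    )


@dataclass
class PathwayClearances:
    """Per-pathway, per-organ intrinsic clearances plus the systemic
    clearances and fm table derived from them.

    ``clint_liver`` / ``clint_kidney`` hold whole-organ unbound intrinsic
    clearances (L/h) for the metabolic pathways; excretory routes are
    plasma clearances taken as observed.  ``cl_plasma`` (filled by
    :func:`aopbpk.clearance.predict_systemic`) holds systemic plasma
    clearance per pathway, and ``fm`` the shares of total systemic
    clearance.
    """

    compound: CompoundRecord
    clint_liver: dict[str, float]
    clint_kidney: dict[str, float] = field(default_factory=dict)
    cl_renal_excretion: float = 0.0  # plasma L/h, observed
    cl_biliary: float = 0.0
    provenance: str = "bottom-up"
    bp: float = 1.0
    # populated by predict_systemic:
    fg: float = 1.0
    fh: float = 1.0
    cl_blood: dict[str, float] = field(default_factory=dict)
    cl_plasma: dict[str, float] = field(default_factory=dict)
    fm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for tbl in (self.clint_liver, self.clint_kidney):
            for p, v in tbl.items():
                if v < 0:
                    raise ValueError(f"negative CLint for {p}")
        if self.clint_kidney and PATH_AO not in self.clint_liver:
            raise ValueError("kidney AO requires a liver AO pathway")

    @property
    def fu_b(self) -> float:
        return self.compound.fu_p / self.bp

    @property
    def clint_liver_total(self) -> float:
        return sum(self.clint_liver.values())

    @property
    def clint_kidney_total(self) -> float:
        return sum(self.clint_kidney.values())

    @property
    def cl_total_plasma(self) -> float:
        return sum(self.cl_plasma.values())

    def metabolic_fm(self) -> dict[str, float]:
        """Pathway shares of *metabolic* (non-excretory) clearance, split
        by organ for AO (liver vs kidney)."""
        met = {
            k: v
            for k, v in self.cl_plasma.items()
            if k not in (PATH_RENAL, PATH_BILIARY)
        }
        total = sum(met.values())
        if total <= 0:
            raise ValueError("no metabolic clearance")
        return {k: v / total for k, v in met.items()}


def assemble_pathways(
    compound: CompoundRecord,
    phys: SystemPhysiology,
    source: str = "HLM+HLC",
    esf: Optional[ESFPolicy] = None,
    bp_conc: Optional[float] = None,
    include_kidney_ao: bool = True,
) -> PathwayClearances:
    """Build the full pathway-clearance network for a compound by IVIVE.

    ``source`` selects the in vitro basis: ``"HLM+HLC"`` assigns the
    cytosolic entry to AO and the microsomal entry to CYP3A4; ``"HH"``
    uses the hepatocyte AO / non-AO split.  Kidney AO is added from the
    AO entry, renal excretion from the observed renal clearance.
    Systemic clearances and the fm table are computed with the
    well-stirred liver/kidney models (see
    :func:`aopbpk.clearance.predict_systemic`).

    ``bp_conc`` is the plasma concentration (ng/mL) at which a
    concentration-dependent blood-to-plasma ratio is queried; by default
    the geometric-mid tabulated point is replaced by the single value for
    single-point tables.
    """
    from . import clearance  # circular-free: clearance does not import ivive at runtime

    esf = esf or ESFPolicy()
    src = source.upper().replace("-", "+").replace("_", "+")
    if src in ("HLM+HLC", "HLC+HLM"):
        ao_entry = compound.entry(InVitroSystem.HLC, Pathway.AO)
        cyp_entry = compound.entry(InVitroSystem.HLM, Pathway.NON_AO)
    elif src == "HH":
        ao_entry = compound.entry(InVitroSystem.HH, Pathway.AO)
        cyp_entry = compound.entry(InVitroSystem.HH, Pathway.NON_AO)
    else:
        raise ConfigurationError(f"unknown in vitro source {source!r}")

    clint_liver = {
        PATH_AO: scale_clint_organ(ao_entry, "liver", phys, esf),
        PATH_CYP3A4: scale_clint_organ(cyp_entry, "liver", phys, esf),
    }
    clint_kidney = {}
    if include_kidney_ao and clint_liver[PATH_AO] > 0:
        clint_kidney[PATH_AO] = scale_clint_organ(ao_entry, "kidney", phys, esf)

    pc = PathwayClearances(
        compound=compound,
        clint_liver=clint_liver,
        clint_kidney=clint_kidney,
        cl_renal_excretion=compound.cl_renal_obs,
        cl_biliary=compound.cl_biliary,
        provenance="bottom-up" if esf.enabled else "bottom-up (no ESF)",
        bp=compound.bp.at(bp_conc) if bp_conc is not None else _default_bp(compound),
    )
    clearance.predict_systemic(pc, phys)
    return pc


def _default_bp(compound: CompoundRecord) -> float:
    """B/P when no query concentration is given: single-point tables
    return their value; multi-point tables are queried at the predicted
    Cmax of the compound's standard regimen (see
    :func:`aopbpk.clearance.resolve_bp_concentration`)."""
    pts = compound.bp.points
    if len(pts) == 1:
        return pts[0][1]
    from . import clearance

    return compound.bp.at(clearance.resolve_bp_concentration(compound))


def compute_fm(pc: PathwayClearances) -> dict[str, float]:
    """Fraction of total systemic plasma clearance per pathway; the
    kidney-AO organ split is folded into the AO pathway here."""
    total = pc.cl_total_plasma
    if total <= 0:
        raise ValueError("total clearance is zero; fm undefined")
    fm: dict[str, float] = {}
    for key, cl in pc.cl_plasma.items():
        path = key.split(":")[0]
        fm[path] = fm.get(path, 0.0) + cl / total
    assert abs(sum(fm.values()) - 1.0) < FM_TOL
    return fm
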