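"""Steady-state organ clearance algebra and model construction modes.

All organ models operate on blood concentrations (``fu_B = fu_p/(B/P)``)
and use the well-stirred approximation; reporting is on the plasma scale
(``CL_p = CL_b * B/P``).  Gut first-pass availability follows the Qgut
model with gut CYP3A4 intrinsic clearance tied to the hepatic CYP3A4
pathway by a fixed abundance ratio.

Model construction modes
------------------------
bottom-up        pure IVIVE (see :func:`aopbpk.ivive.assemble_pathways`)
middle-out-fm    bottom-up total CLint,u redistributed to observed fm
middle-out-CL    CLint,u back-calculated from observed clearance,
                 pathway split kept from prediction
top-down         CLint,u from observed clearance, split by observed fm
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from scipy.optimize import brentq

from .compounds import CompoundRecord, ConfigurationError, predict_peff
from .ivive import (
    METABOLIC_PATHWAYS,
    PATH_AO,
    PATH_BILIARY,
    PATH_CYP3A4,
    PATH_RENAL,
    PathwayClearances,
    compute_fm,
    kidney_to_liver_ao_ratio,
)
from .physiology import SystemPhysiology

#: effective absorptive surface area of the small intestine used when the
#: Qgut term must be predicted from permeability (m^2)
GUT_SURFACE_AREA_M2 = 0.66

RETROGRADE_RTOL = 1e-9


class InfeasibleClearanceError(ValueError):
    """Observed blood clearance at or above the organ flow limit."""


def well_stirred_cl(q: float, fu_b: float, clint_u: float) -> float:
    """Well-stirred organ blood clearance: ``Q*fu_B*CLint,u/(Q + fu_B*CLint,u)``."""
    if q <= 0:
        raise ValueError("organ blood flow must be positive")
    if clint_u < 0:
        raise ValueError("CLint,u must be non-negative")
    x = fu_b * clint_u
    return q * x / (q + x)


def hepatic_availability(q: float, fu_b: float, clint_u: float) -> float:
    """Fraction escaping hepatic first pass, ``F_H = Q/(Q + fu_B*CLint,u)``."""
    if q <= 0:
        raise ValueError("organ blood flow must be positive")
    return q / (q + fu_b * clint_u)


def qgut_fg(qgut: float, fu_gut: float, clint_gut_u: float) -> float:
    """Fraction escaping gut metabolism, ``Fg = Qgut/(Qgut + fu_gut*CLint,gut,u)``."""
    if qgut <= 0:
        raise ValueError("Qgut must be positive")
    if clint_gut_u < 0:
        raise ValueError("gut CLint,u must be non-negative")
    return qgut / (qgut + fu_gut * clint_gut_u)


def predict_qgut(papp: float, phys: SystemPhysiology) -> float:
    """Qgut (L/h) from apparent permeability when no value is supplied:
    ``Qgut = Q_villi*CL_perm/(Q_villi + CL_perm)`` with
    ``CL_perm = Peff*A``."""
    peff = predict_peff(papp)  # 1e-4 cm/s
    cl_perm = peff * 1e-4 * 3600.0 * GUT_SURFACE_AREA_M2 * 1e4 * 1e-3  # L/h
    qv = phys.villous_blood_flow
    return qv * cl_perm / (qv + cl_perm)


def _gut_clint(pc: PathwayClearances, phys: SystemPhysiology) -> float:
    return phys.gut_to_liver_cyp3a4_ratio * pc.clint_liver.get(PATH_CYP3A4, 0.0)


def compute_fg(pc: PathwayClearances, phys: SystemPhysiology) -> float:
    """Gut availability for the compound's oral absorption; 1 for drugs
    without an oral absorption model."""
    compound = pc.compound
    if compound.fa is None:
        return 1.0
    qgut = compound.qgut
    if qgut is None:
        if compound.papp is None:
            return 1.0
        qgut = predict_qgut(compound.papp, phys)
    return qgut_fg(qgut, compound.effective_fu_gut, _gut_clint(pc, phys))


def predict_systemic(pc: PathwayClearances, phys: SystemPhysiology) -> dict:
    """Forward prediction of systemic clearance from a pathway network.

    Fills ``pc.cl_blood``, ``pc.cl_plasma`` (keys ``"AO:liver"``,
    ``"AO:kidney"``, ``"CYP3A4:liver"``, ``"renal_excretion"``,
    ``"biliary"``), ``pc.fg``, ``pc.fh`` and ``pc.fm``, and returns
    ``{"cl_iv": L/h plasma, "cl_over_f": L/h, "f": fraction}``.

    Within an organ the well-stirred clearance of the summed intrinsic
    clearance is split across pathways in proportion to their CLint,u.
    """
    compound = pc.compound
    fu_b = pc.fu_b
    cl_blood: dict[str, float] = {}

    liver_total = pc.clint_liver_total
    cl_h_b = well_stirred_cl(phys.hepatic_blood_flow, fu_b, liver_total)
    for path, clint in pc.clint_liver.items():
        if clint > 0:
            cl_blood[f"{path}:liver"] = cl_h_b * clint / liver_total
    pc.fh = hepatic_availability(phys.hepatic_blood_flow, fu_b, liver_total)

    kidney_total = pc.clint_kidney_total
    if kidney_total > 0:
        cl_k_b = well_stirred_cl(phys.renal_blood_flow, fu_b, kidney_total)
        for path, clint in pc.clint_kidney.items():
            if clint > 0:
                cl_blood[f"{path}:kidney"] = cl_k_b * clint / kidney_total

    pc.cl_blood = cl_blood
    pc.cl_plasma = {k: v * pc.bp for k, v in cl_blood.items()}
    if pc.cl_renal_excretion > 0:
        pc.cl_plasma[PATH_RENAL] = pc.cl_renal_excretion
        pc.cl_blood[PATH_RENAL] = pc.cl_renal_excretion / pc.bp
    if pc.cl_biliary > 0:
        pc.cl_plasma[PATH_BILIARY] = pc.cl_biliary
        pc.cl_blood[PATH_BILIARY] = pc.cl_biliary / pc.bp

    pc.fg = compute_fg(pc, phys)
    pc.fm = compute_fm(pc) if pc.cl_total_plasma > 0 else {}

    cl_iv = pc.cl_total_plasma
    out = {"cl_iv": cl_iv, "cl_over_f": None, "f": None}
    if compound.fa is not None:
        f = compound.fa * pc.fg * pc.fh
        if f <= 0:
            raise ValueError("oral bioavailability is zero; CL/F undefined")
        out["f"] = f
        out["cl_over_f"] = cl_iv / f
    return out


def predicted_cl(pc: PathwayClearances, route: Optional[str] = None) -> float:
    """Systemic plasma clearance on the requested route (``CL`` for iv,
    ``CL/F`` for oral); defaults to the route of the observed clearance."""
    from .physiology import default_physiology

    if not pc.cl_plasma:
        predict_systemic(pc, default_physiology())
    route = route or (pc.compound.cl_obs.route if pc.compound.cl_obs else "iv")
    if route == "iv":
        return pc.cl_total_plasma
    f = pc.compound.fa * pc.fg * pc.fh
    return pc.cl_total_plasma / f


def resolve_bp_concentration(
    compound: CompoundRecord, phys: Optional[SystemPhysiology] = None
) -> float:
    """Query concentration (ng/mL) for a concentration-dependent B/P
    table: the predicted Cmax of the compound's standard regimen,
    simulated once with the B/P of the first tabulated point."""
    from .ivive import ESFPolicy, assemble_pathways
    from .pbpk import simulate_minimal
    from .physiology import default_physiology

    phys = phys or default_physiology()
    if compound.regimen is None:
        raise ConfigurationError(
            f"{compound.name}: concentration-dependent B/P needs a regimen "
            "or an explicit query concentration"
        )
    provisional = assemble_pathways(
        compound, phys, source="HLM+HLC", esf=ESFPolicy(),
        bp_conc=compound.bp.points[0][0],
    )
    profile = simulate_minimal(compound, phys, provisional, compound.regimen)
    return profile.cmax * 1000.0  # mg/L -> ng/mL


# ---------------------------------------------------------------------------
# retrograde (middle-out / top-down)


@dataclass
class RetrogradeResult:
    """Back-calculated in vivo intrinsic clearance."""

    clint_liver_total: float  # L/h, unbound, whole liver
    clint_liver: dict[str, float]
    clint_kidney: dict[str, float]
    per_mg_cytosolic: Optional[float]  # uL/min/mg, AO pathway
    per_mg_microsomal: Optional[float]  # uL/min/mg, CYP3A4 pathway
    pathway_clearances: PathwayClearances


def _normalize_fm(fm: Optional[dict], compound: CompoundRecord) -> dict[str, float]:
    """Metabolic pathway split used to apportion back-calculated CLint,u.

    ``None`` attributes all metabolism to AO (the conservative reading for
    AO-cleared drugs without phenotyping data).  Excretory entries in an
    observed fm table are ignored here: only the relative metabolic split
    matters."""
    if fm is None:
        return {PATH_AO: 1.0}
    met = {k: v for k, v in fm.items() if k in METABOLIC_PATHWAYS and v > 0}
    if not met:
        raise ValueError("fm table has no metabolic pathway")
    total = sum(met.values())
    return {k: v / total for k, v in met.items()}


def retrograde_clint(
    cl_obs: float,
    route: str,
    compound: CompoundRecord,
    phys: SystemPhysiology,
    fm: Optional[dict[str, float]] = None,
    bp_conc: Optional[float] = None,
    include_kidney_ao: bool = True,
    provenance: Optional[str] = None,
) -> RetrogradeResult:
    """Back-calculate total in vivo unbound intrinsic clearance from an
    observed plasma clearance.

    Observed renal (and biliary) excretory clearance is subtracted, the
    remainder attributed to liver plus (for the AO share) kidney
    metabolism, and the joint well-stirred system inverted for the total
    liver CLint,u.  Oral observations (CL/F) fold in fa, the Qgut-model
    Fg and hepatic availability, all functions of the solved CLint,u, so
    the inversion is a 1-D root find (bracketed, relative tolerance
    1e-9).  A supplied ``fm`` table splits the metabolic CLint,u across
    pathways proportionally; kidney AO is tied to liver AO by the
    relative-abundance ratio.
    """
    if cl_obs <= 0:
        raise ValueError("observed clearance must be positive")
    if route not in ("iv", "oral"):
        raise ValueError(f"route must be 'iv' or 'oral', got {route!r}")
    if route == "oral" and compound.fa is None:
        raise ConfigurationError(f"{compound.name}: oral retrograde needs fa")

    bp = compound.bp.at(bp_conc) if bp_conc is not None or len(compound.bp.points) == 1 \
        else compound.bp.at(resolve_bp_concentration(compound, phys))
    fu_b = compound.fu_p / bp
    split = _normalize_fm(fm, compound)
    ao_share = split.get(PATH_AO, 0.0)
    r_kidney = kidney_to_liver_ao_ratio(phys) if (include_kidney_ao and ao_share > 0) else 0.0
    cl_excret = compound.cl_renal_obs + compound.cl_biliary
    qh, qk = phys.hepatic_blood_flow, phys.renal_blood_flow

    def build(x: float) -> PathwayClearances:
        clint_liver = {p: f * x for p, f in split.items()}
        clint_kidney = (
            {PATH_AO: r_kidney * ao_share * x} if r_kidney > 0 else {}
        )
        return PathwayClearances(
            compound=compound,
            clint_liver=clint_liver,
            clint_kidney=clint_kidney,
            cl_renal_excretion=compound.cl_renal_obs,
            cl_biliary=compound.cl_biliary,
            bp=bp,
        )

    if route == "iv":
        target_met = cl_obs - cl_excret
        if target_met <= 0:
            raise ValueError(
                "observed clearance does not exceed excretory clearance; "
                "no metabolic CLint,u to recover"
            )
        limit = (qh + (qk if r_kidney > 0 else 0.0)) * bp
        if target_met >= limit:
            raise InfeasibleClearanceError(
                f"metabolic plasma clearance {target_met:.3g} L/h is at/above the "
                f"organ flow limit {limit:.3g} L/h; a hepatic blood flow of at "
                f"least {target_met / bp:.3g} L/h would be required"
            )

        def objective(x: float) -> float:
            cl = well_stirred_cl(qh, fu_b, x)
            if r_kidney > 0:
                cl += well_stirred_cl(qk, fu_b, r_kidney * ao_share * x)
            return cl * bp - target_met

    else:  # oral: match CL/F

        def objective(x: float) -> float:
            pc = build(x)
            out = predict_systemic(pc, phys)
            return out["cl_over_f"] - cl_obs

    # bracket: objective is strictly increasing in x
    lo, hi = 0.0, 1.0
    while objective(hi) < 0:
        hi *= 4.0
        if hi > 1e15:
            raise InfeasibleClearanceError("no CLint,u reproduces the observed clearance")
    x = brentq(objective, lo, hi, rtol=RETROGRADE_RTOL, maxiter=200)

    pc = build(x)
    predict_systemic(pc, phys)
    pc.provenance = provenance or ("top-down" if fm is not None else "middle-out-CL")

    ao_clint = pc.clint_liver.get(PATH_AO, 0.0)
    cyp_clint = pc.clint_liver.get(PATH_CYP3A4, 0.0)
    denom_c = phys.cppgl * phys.liver_mass * 60e-6
    denom_m = phys.mppgl * phys.liver_mass * 60e-6
    return RetrogradeResult(
        clint_liver_total=x,
        clint_liver=dict(pc.clint_liver),
        clint_kidney=dict(pc.clint_kidney),
        per_mg_cytosolic=ao_clint / denom_c if ao_clint > 0 else None,
        per_mg_microsomal=cyp_clint / denom_m if cyp_clint > 0 else None,
        pathway_clearances=pc,
    )


def middle_out_fm(
    pc: PathwayClearances, fm: dict[str, float], phys: SystemPhysiology
) -> PathwayClearances:
    """Redistribute a bottom-up model's total liver CLint,u to an observed
    metabolic fm split, leaving the total unchanged (and therefore total
    clearance essentially unchanged)."""
    split = _normalize_fm(fm, pc.compound)
    total = pc.clint_liver_total
    clint_liver = {p: f * total for p, f in split.items()}
    ao = clint_liver.get(PATH_AO, 0.0)
    clint_kidney = (
        {PATH_AO: kidney_to_liver_ao_ratio(phys) * ao} if (pc.clint_kidney and ao > 0) else {}
    )
    new = PathwayClearances(
        compound=pc.compound,
        clint_liver=clint_liver,
        clint_kidney=clint_kidney,
        cl_renal_excretion=pc.cl_renal_excretion,
        cl_biliary=pc.cl_biliary,
        provenance="middle-out-fm",
        bp=pc.bp,
    )
    predict_systemic(new, phys)
    return new
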