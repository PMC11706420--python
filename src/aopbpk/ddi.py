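"""Drug-drug interaction prediction for AO and dual AO-CYP3A4 substrates.

The mechanistic static model multiplies each affected pathway's
clearance by a net factor combining reversible inhibition,
time-dependent inactivation (against enzyme turnover ``kdeg``) and
induction, and converts the fraction-metabolized table of the victim
into an AUC ratio:

    AUCR = 1 / ( sum_i fm_i * x_i  +  (1 - sum_i fm_i) )
    x_i  = [1/(1+I/Ki)] * [kdeg/(kdeg + kinact*I/(KI+I))] * [1 + d*Indmax*I/(IndC50+I)]

with ``I`` the unbound inhibitor exposure (hepatic-inlet or systemic
Cmax,u).  The dynamic variant co-simulates the victim with an explicit
enzyme-amount ODE and converges to the static result when the inhibitor
exposure is constant.

Perpetrator kinetic constants are user-supplied: inhibition constants
for clinical CYP3A4/AO perpetrators vary between laboratories and should
be verified against primary sources before use.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from pydantic import BaseModel, Field, model_validator
from .compounds import CompoundRecord, DoseRegimen
from .ivive import PATH_AO, PATH_BILIARY, PATH_CYP3A4, PATH_RENAL, PathwayClearances
from .pbpk import simulate_minimal
from .physiology import KDEG_DEFAULT_PER_MIN, SystemPhysiology, default_physiology

FM_SUM_TOL = 1e-9


class TDIParams(BaseModel):
    """Time-dependent inactivation: ``kinact`` (1/min) and unbound ``KI``
    (same concentration units as the exposure)."""

    ki_u: float = Field(gt=0.0)
    kinact: float = Field(gt=0.0)


class InductionParams(BaseModel):
    ind_max: float = Field(gt=0.0)
    indc50: float = Field(gt=0.0)
    d: float = Field(default=1.0, gt=0.0)


class PerpetratorParams(BaseModel):
    """Kinetic and exposure parameters of a perpetrator drug.

    ``reversible_ki_u`` maps enzyme name (``"AO"``, ``"CYP3A4"``) to the
    unbound inhibition constant, either a scalar or a ``(min, max)``
    range (a range propagates to an AUCR band).  Concentration units must
    match ``cmax`` (mg/L by package convention; any unit works if used
    consistently).
    """

    name: str
    dose: Optional[float] = Field(default=None, gt=0.0)  # mg
    cmax: float = Field(gt=0.0)  # plasma, mg/L
    fu_p: float = Field(gt=0.0, le=1.0)
    bp: float = Field(default=1.0, gt=0.0)
    ka: Optional[float] = Field(default=None, gt=0.0)  # 1/h
    fa_fg: Optional[float] = Field(default=None, gt=0.0, le=1.0)
    reversible_ki_u: dict[str, Union[float, tuple[float, float]]] = Field(
        default_factory=dict
    )
    tdi: dict[str, TDIParams] = Field(default_factory=dict)
    induction: dict[str, InductionParams] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_ki(self):
        for enz, ki in self.reversible_ki_u.items():
            vals = ki if isinstance(ki, tuple) else (ki,)
            if any(v <= 0 for v in vals):
                raise ValueError(f"Ki,u for {enz} must be positive")
            if len(vals) == 2 and vals[0] > vals[1]:
                raise ValueError(f"Ki,u range for {enz} must be (min, max)")
        return self

    def ki_point(self, enzyme: str) -> Optional[float]:
        """Scalar Ki,u (geometric mid of a range)."""
        ki = self.reversible_ki_u.get(enzyme)
        if ki is None:
            return None
        if isinstance(ki, tuple):
            return math.sqrt(ki[0] * ki[1])
        return ki

    @property
    def has_ki_range(self) -> bool:
        return any(isinstance(k, tuple) for k in self.reversible_ki_u.values())


class DDICategory(str, enum.Enum):
    NONE = "none"
    WEAK = "weak"
    MODERATE = "moderate"
    STRONG = "strong"


def classify_ddi(aucr: float) -> DDICategory:
    """Regulatory magnitude class; inducers (AUCR < 1) are classified on
    the reciprocal ratio."""
    if aucr <= 0:
        raise ValueError("AUCR must be positive")
    r = aucr if aucr >= 1.0 else 1.0 / aucr
    if r >= 5.0:
        return DDICategory.STRONG
    if r >= 2.0:
        return DDICategory.MODERATE
    if r >= 1.25:
        return DDICategory.WEAK
    return DDICategory.NONE


@dataclass
class DDIResult:
    aucr: float
    multipliers: dict[str, dict[str, float]]  # enzyme -> term decomposition
    exposure_u: float
    classification: DDICategory
    aucr_range: Optional[tuple[float, float]] = None
    detail: dict = field(default_factory=dict)


def inlet_exposure(
    perp: PerpetratorParams,
    phys: Optional[SystemPhysiology] = None,
    mode: str = "inlet",
) -> float:
    """Unbound perpetrator exposure driving the static model.

    ``"inlet"`` is the unbound hepatic-inlet maximum,
    ``fu_B*(Cmax*B/P + fa*Fg*ka*Dose/Q_H)`` (conservative for hepatic
    interactions); ``"systemic"`` is the unbound systemic Cmax
    ``fu_p*Cmax`` — the basis of the AO exposure-margin screen.
    """
    phys = phys or default_physiology()
    if mode == "systemic":
        return perp.fu_p * perp.cmax
    if mode != "inlet":
        raise ValueError(f"unknown exposure mode {mode!r}")
    i_h_b = perp.cmax * perp.bp
    if perp.dose is not None and perp.ka is not None and perp.fa_fg is not None:
        i_h_b += perp.fa_fg * perp.ka * perp.dose / phys.hepatic_blood_flow
    fu_b = perp.fu_p / perp.bp
    return fu_b * i_h_b


def exposure_margin(perp: PerpetratorParams, enzyme: str = PATH_AO) -> Optional[float]:
    """Cmax,u / Ki,u screening margin for the given enzyme."""
    ki = perp.ki_point(enzyme)
    if ki is None:
        return None
    return perp.fu_p * perp.cmax / ki


def _net_multiplier(
    perp: PerpetratorParams,
    enzyme: str,
    exposure: float,
    kdeg_per_min: float,
    ki_override: Optional[float] = None,
) -> dict[str, float]:
    rev = tdi = ind = 1.0
    ki = ki_override if ki_override is not None else perp.ki_point(enzyme)
    if ki is not None:
        rev = 1.0 / (1.0 + exposure / ki)
    if enzyme in perp.tdi:
        p = perp.tdi[enzyme]
        tdi = kdeg_per_min / (kdeg_per_min + p.kinact * exposure / (p.ki_u + exposure))
    if enzyme in perp.induction:
        p = perp.induction[enzyme]
        ind = 1.0 + p.d * p.ind_max * exposure / (p.indc50 + exposure)
    return {"reversible": rev, "tdi": tdi, "induction": ind, "net": rev * tdi * ind}


def static_aucr(
    fm: dict[str, float],
    perp: PerpetratorParams,
    exposure: float,
    kdeg_per_min: float = KDEG_DEFAULT_PER_MIN,
) -> DDIResult:
    """Mechanistic static AUC ratio from the victim fm table.

    ``fm`` maps enzyme names to fractions of total systemic clearance
    (excretory entries are ignored as unaffected routes).  A Ki,u range
    on any enzyme yields an ``aucr_range`` alongside the point estimate.
    """
    enzymes = [k for k in fm if k not in (PATH_RENAL, PATH_BILIARY)]
    fm_sum = sum(fm[k] for k in enzymes)
    if fm_sum > 1.0 + FM_SUM_TOL:
        raise ValueError(f"fm fractions sum to {fm_sum:.4f} > 1")
    if exposure < 0:
        raise ValueError("exposure must be non-negative")

    def compute(ki_side: Optional[int]) -> tuple[float, dict]:
        mult = {}
        denom = 1.0 - fm_sum
        for enz in enzymes:
            override = None
            ki = perp.reversible_ki_u.get(enz)
            if ki_side is not None and isinstance(ki, tuple):
                override = ki[ki_side]
            mult[enz] = _net_multiplier(perp, enz, exposure, kdeg_per_min, override)
            denom += fm[enz] * mult[enz]["net"]
        return 1.0 / denom, mult

    aucr, multipliers = compute(None)
    aucr_range = None
    if perp.has_ki_range:
        hi, _ = compute(0)  # smallest Ki -> strongest inhibition
        lo, _ = compute(1)
        aucr_range = (min(lo, hi), max(lo, hi))
    return DDIResult(
        aucr=aucr,
        multipliers=multipliers,
        exposure_u=exposure,
        classification=classify_ddi(aucr),
        aucr_range=aucr_range,
    )


# ---------------------------------------------------------------------------
# dynamic (enzyme-turnover) co-simulation


ExposureLike = Union[float, tuple[np.ndarray, np.ndarray], Callable[[float], float]]


def _exposure_fn(exposure_u: ExposureLike) -> tuple[Callable[[float], float], bool]:
    if callable(exposure_u):
        return exposure_u, False
    if isinstance(exposure_u, (int, float)):
        v = float(exposure_u)
        return (lambda t: v), True
    times, conc = (np.asarray(a, dtype=float) for a in exposure_u)
    return (lambda t: float(np.interp(t, times, conc))), False


def dynamic_aucr(
    compound: CompoundRecord,
    pc: PathwayClearances,
    perp: PerpetratorParams,
    phys: SystemPhysiology,
    regimen: DoseRegimen,
    exposure_u: ExposureLike,
    kdeg_per_min: Optional[float] = None,
    tgrid: Optional[np.ndarray] = None,
) -> DDIResult:
    """Victim AUC ratio from paired simulations with explicit enzyme
    turnover.

    ``exposure_u`` is the unbound perpetrator concentration: a constant,
    a ``(times, conc)`` table, or a callable of time.  Affected liver
    (and kidney, for AO) pathway intrinsic clearances are scaled by
    ``(E/E0) / (1 + I_u/Ki)`` with the enzyme amount obeying

        dE/dt = kdeg*E0*(1 + d*Indmax*Iu/(IndC50+Iu)) - E*(kdeg + kinact*Iu/(KI+Iu))

    For a constant exposure the enzyme pool starts at its steady state
    (pre-equilibrated perpetrator dosing) and the result matches the
    static model.
    """
    kdeg = (kdeg_per_min if kdeg_per_min is not None else phys.kdeg_enzyme) * 60.0  # 1/h
    i_u, constant = _exposure_fn(exposure_u)

    enzymes = sorted(
        set(pc.clint_liver)
        & (set(perp.reversible_ki_u) | set(perp.tdi) | set(perp.induction))
    )
    baseline = simulate_minimal(compound, phys, pc, regimen, tgrid)
    base_auc = baseline.metrics().auc_inf
    if not enzymes:
        return DDIResult(
            aucr=1.0, multipliers={}, exposure_u=i_u(0.0),
            classification=DDICategory.NONE,
        )

    def synth_rate(iu: float, enz: str) -> float:
        rate = kdeg
        if enz in perp.induction:
            p = perp.induction[enz]
            rate *= 1.0 + p.d * p.ind_max * iu / (p.indc50 + iu)
        return rate

    def deg_rate(iu: float, enz: str) -> float:
        rate = kdeg
        if enz in perp.tdi:
            p = perp.tdi[enz]
            rate += p.kinact * 60.0 * iu / (p.ki_u + iu)
        return rate

    def e_init(enz: str) -> float:
        if not constant:
            return 1.0
        iu0 = i_u(0.0)
        return synth_rate(iu0, enz) / deg_rate(iu0, enz)

    # victim minimal-PBPK states + one enzyme state per affected enzyme
    dist = compound.distribution
    bw = phys.body_weight
    v_c = (dist.vss - dist.vsac) * bw
    v_sac = dist.vsac * bw
    q_sac = dist.q_intercompartment
    oral = regimen.route == "oral"
    ka = compound.ka if oral else 0.0
    qh, qk = phys.hepatic_blood_flow, phys.renal_blood_flow
    fu_b = pc.fu_b
    bp = pc.bp
    cl_excret = pc.cl_renal_excretion + pc.cl_biliary

    from .pbpk import _dose_events, _integrate_events  # shared machinery

    if tgrid is None:
        tgrid = baseline.times

    def scaled_cl(t, e_amounts):
        """instantaneous (CL_total_plasma, F_H, Fg) under inhibition"""
        iu = i_u(t)
        liver = {}
        for path, clint in pc.clint_liver.items():
            s = 1.0
            if path in enzymes:
                idx = enzymes.index(path)
                s = e_amounts[idx]
                ki = perp.ki_point(path)
                if ki is not None:
                    s /= 1.0 + iu / ki
            liver[path] = clint * s
        kidney = {}
        for path, clint in pc.clint_kidney.items():
            s = 1.0
            if path in enzymes:
                idx = enzymes.index(path)
                s = e_amounts[idx]
                ki = perp.ki_point(path)
                if ki is not None:
                    s /= 1.0 + iu / ki
            kidney[path] = clint * s
        lt = sum(liver.values())
        kt = sum(kidney.values())
        cl_b = qh * fu_b * lt / (qh + fu_b * lt)
        if kt > 0:
            cl_b += qk * fu_b * kt / (qk + fu_b * kt)
        fh = qh / (qh + fu_b * lt)
        fg_clint = phys.gut_to_liver_cyp3a4_ratio * liver.get(PATH_CYP3A4, 0.0)
        if compound.qgut is not None and oral:
            fg = compound.qgut / (compound.qgut + compound.effective_fu_gut * fg_clint)
        else:
            fg = pc.fg
        return cl_b * bp + cl_excret, fh, fg

    def rhs_factory(rate):
        def rhs(t, y):
            a_a, a_c, a_sac, a_el = y[:4]
            e = y[4:]
            iu = i_u(t)
            cl, fh, fg = scaled_cl(t, e)
            c = a_c / v_c
            exch = q_sac * (c - a_sac / v_sac) if (q_sac > 0 and v_sac > 0) else 0.0
            absorbed = ka * a_a
            first_pass = fg * fh if oral else 1.0
            de = [
                synth_rate(iu, enz) - deg_rate(iu, enz) * e[j]
                for j, enz in enumerate(enzymes)
            ]
            return (
                -absorbed,
                absorbed * first_pass + rate - cl * c - exch,
                exch,
                cl * c,
                *de,
            )

        return rhs

    def apply_instant(y, kind, value):
        y = y.copy()
        if kind == "depot":
            y[0] += compound.fa * value
        elif kind == "bolus":
            y[1] += value
        return y

    events = _dose_events(regimen, compound.t_lag if oral else 0.0)
    y0 = [0.0, 0.0, 0.0, 0.0] + [e_init(enz) for enz in enzymes]
    y = _integrate_events(rhs_factory, y0, events, np.asarray(tgrid), apply_instant)
    from .pbpk import PKProfile

    perturbed = PKProfile(
        times=np.asarray(tgrid), conc=y[1] / v_c, regimen=regimen,
        compound_name=compound.name,
    )
    pert_auc = perturbed.metrics().auc_inf
    aucr = pert_auc / base_auc
    mult = {
        enz: _net_multiplier(perp, enz, i_u(0.0), kdeg / 60.0) for enz in enzymes
    }
    return DDIResult(
        aucr=aucr,
        multipliers=mult,
        exposure_u=i_u(0.0),
        classification=classify_ddi(aucr),
        detail={"auc_base": base_auc, "auc_perturbed": pert_auc},
    )
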