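"""Plasma concentration-time simulation and non-compartmental metrics.

Two distribution models are provided:

* **minimal PBPK** — a central compartment (``Vc = Vss - Vsac``) plus a
  single adjusting compartment (SAC) exchanging with inter-compartment
  clearance Q; first-order oral absorption with lag time.  Hepatic and
  gut first pass are applied as the scalar ``Fg*F_H`` on the absorption
  flux, which leaves AUC and clearance identical to an explicit
  portal/liver chain while keeping the system small.
* **full PBPK** — perfusion-limited tissue compartments (adipose,
  muscle, liver, kidney, rest) with user-supplied tissue:plasma
  partition coefficients; the liver is the clearing tissue.

Elimination in both models is the systemic plasma clearance of the
pathway network, so the engine and the steady-state clearance algebra
are mutually consistent (an invariant exercised by the test suite).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .compounds import CompoundRecord, DoseRegimen
from .ivive import PathwayClearances
from .physiology import SystemPhysiology

logger = logging.getLogger(__name__)

ODE_RTOL = 1e-8
ODE_ATOL = 1e-12

#: reduced tissue set for the full model: fractional body volumes (L/kg)
#: and blood flows (L/h) for a 70-kg adult, scaled by body weight ratio
FULL_MODEL_TISSUES = {
    "adipose": {"volume": 13.0 / 70.0, "flow": 15.6},
    "muscle": {"volume": 29.0 / 70.0, "flow": 45.0},
    "liver": {"volume": 1.65 / 70.0, "flow": 97.0},
    "kidney": {"volume": 0.31 / 70.0, "flow": 66.0},
    "rest": {"volume": 20.84 / 70.0, "flow": 166.4},
}
BLOOD_VOLUME_L_PER_KG = 5.2 / 70.0
VENOUS_FRACTION = 0.70


class ExtrapolationError(RuntimeError):
    """Terminal phase unsuitable for AUC extrapolation; AUC_t is attached."""

    def __init__(self, message: str, auc_t: float):
        super().__init__(message)
        self.auc_t = auc_t


@dataclass
class PKMetrics:
    cmax: float
    tmax: float
    auc_t: float
    auc_inf: Optional[float]
    lambda_z: Optional[float]
    t_half: Optional[float]
    cl_or_clf: Optional[float]  # dose/AUC_inf


@dataclass
class PKProfile:
    """Concentration-time profile (plasma, mg/L) for one regimen."""

    times: np.ndarray  # h
    conc: np.ndarray  # mg/L
    regimen: DoseRegimen
    compound_name: str = ""
    amounts: Optional[dict[str, np.ndarray]] = field(default=None, repr=False)
    dose_to_system: Optional[float] = None  # mg actually reaching circulation

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.shape != self.conc.shape:
            raise ValueError("times and conc must have the same shape")
        if np.any(self.conc < -1e-9):
            raise ValueError("negative concentrations")
        self.conc = np.clip(self.conc, 0.0, None)

    @property
    def cmax(self) -> float:
        return float(self.conc.max())

    @property
    def tmax(self) -> float:
        return float(self.times[int(self.conc.argmax())])

    def metrics(self, n_terminal: int = 3) -> PKMetrics:
        return pk_metrics(self, n_terminal=n_terminal)


# ---------------------------------------------------------------------------
# dosing helpers


def _dose_events(regimen: DoseRegimen, t_lag: float):
    """(time, kind, value) events: depot/bolus additions and infusion
    rate switches."""
    events = []
    for i in range(regimen.n_doses):
        t0 = i * (regimen.interval or 0.0)
        if regimen.route == "oral":
            events.append((t0 + t_lag, "depot", regimen.dose))
        elif regimen.route == "iv-bolus":
            events.append((t0, "bolus", regimen.dose))
        else:
            rate = regimen.dose / regimen.infusion_duration
            events.append((t0, "rate_on", rate))
            events.append((t0 + regimen.infusion_duration, "rate_off", rate))
    return sorted(events, key=lambda e: e[0])


def _default_tgrid(regimen: DoseRegimen, cl: float, vss_l: float) -> np.ndarray:
    t_half = math.log(2.0) * vss_l / max(cl, 1e-6)
    last = (regimen.n_doses - 1) * (regimen.interval or 0.0)
    t_end = last + min(max(8.0 * t_half, 12.0), 1000.0)
    return np.linspace(0.0, t_end, 481)


def _integrate_events(rhs_factory, y0, events, tgrid, apply_instant):
    """Piecewise integration over dose-event boundaries with dense output
    resampled onto ``tgrid``."""
    tgrid = np.asarray(tgrid, dtype=float)
    boundaries = sorted({0.0, float(tgrid[-1])} | {t for t, _, _ in events if t < tgrid[-1]})
    y = np.array(y0, dtype=float)
    rate = 0.0
    out = np.zeros((len(y), len(tgrid)))
    filled = np.zeros(len(tgrid), dtype=bool)
    for i, t0 in enumerate(boundaries):
        for t, kind, value in events:
            if abs(t - t0) < 1e-12:
                if kind == "rate_on":
                    rate += value
                elif kind == "rate_off":
                    rate -= value
                else:
                    y = apply_instant(y, kind, value)
        at_boundary = (~filled) & (np.abs(tgrid - t0) < 1e-12)
        if at_boundary.any():
            out[:, at_boundary] = y[:, None]
            filled |= at_boundary
        t1 = boundaries[i + 1] if i + 1 < len(boundaries) else tgrid[-1]
        if t1 <= t0:
            continue
        sol = solve_ivp(
            rhs_factory(rate),
            (t0, t1),
            y,
            method="LSODA",
            dense_output=True,
            rtol=ODE_RTOL,
            atol=ODE_ATOL,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        mask = (~filled) & (tgrid > t0) & (tgrid <= t1)
        if mask.any():
            out[:, mask] = sol.sol(tgrid[mask])
            filled |= mask
        y = sol.y[:, -1]
    return out


# ---------------------------------------------------------------------------
# minimal PBPK


def simulate_minimal(
    compound: CompoundRecord,
    phys: SystemPhysiology,
    pc: PathwayClearances,
    regimen: DoseRegimen,
    tgrid: Optional[np.ndarray] = None,
) -> PKProfile:
    """Simulate the minimal PBPK model (central + SAC + oral depot).

    Oral input reaches the circulation as ``ka*A_a*Fg*F_H``; iv doses
    enter the central compartment directly.  Elimination is the total
    systemic plasma clearance of ``pc``.
    """
    dist = compound.distribution
    bw = phys.body_weight
    v_c = (dist.vss - dist.vsac) * bw
    v_sac = dist.vsac * bw
    q_sac = dist.q_intercompartment
    if v_c <= 0:
        raise ValueError("Vss must exceed Vsac")
    cl = pc.cl_total_plasma
    if not pc.cl_plasma:
        raise ValueError("pathway clearances not populated; run predict_systemic first")

    oral = regimen.route == "oral"
    if oral:
        if compound.fa is None or compound.ka is None:
            raise ValueError(f"{compound.name}: oral simulation needs fa and ka")
        first_pass = pc.fg * pc.fh
        ka = compound.ka
    else:
        first_pass, ka = 1.0, 0.0

    if tgrid is None:
        tgrid = _default_tgrid(regimen, max(cl, 1e-6), dist.vss * bw)

    def rhs_factory(rate):
        def rhs(t, y):
            a_a, a_c, a_sac, _ = y
            c = a_c / v_c
            exch = 0.0
            if q_sac > 0 and v_sac > 0:
                exch = q_sac * (c - a_sac / v_sac)
            absorbed = ka * a_a
            return (
                -absorbed,
                absorbed * first_pass + rate - cl * c - exch,
                exch,
                cl * c,
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
    y = _integrate_events(rhs_factory, [0.0, 0.0, 0.0, 0.0], events, tgrid, apply_instant)
    total_dose = regimen.dose * regimen.n_doses
    dose_sys = total_dose * (compound.fa * first_pass if oral else 1.0)
    return PKProfile(
        times=np.asarray(tgrid),
        conc=y[1] / v_c,
        regimen=regimen,
        compound_name=compound.name,
        amounts={"depot": y[0], "central": y[1], "sac": y[2], "eliminated": y[3]},
        dose_to_system=dose_sys,
    )


# ---------------------------------------------------------------------------
# full PBPK


def uniform_kp_for_vss(compound: CompoundRecord, phys: SystemPhysiology, bp: float) -> dict:
    """Uniform Kp set reproducing the compound's Vss exactly (useful as a
    stand-in when no tissue-composition Kp set is available)."""
    bw = phys.body_weight
    vss_l = compound.distribution.vss * bw
    v_tissue = sum(FULL_MODEL_TISSUES[t]["volume"] * bw for t in FULL_MODEL_TISSUES)
    kp = (vss_l - BLOOD_VOLUME_L_PER_KG * bw * bp) / v_tissue
    if kp <= 0:
        raise ValueError("Vss smaller than blood space; cannot build a Kp set")
    return {t: kp / compound.distribution.kp_scalar for t in FULL_MODEL_TISSUES}


def simulate_full(
    compound: CompoundRecord,
    phys: SystemPhysiology,
    pc: PathwayClearances,
    kp_set: Optional[dict[str, float]],
    regimen: DoseRegimen,
    tgrid: Optional[np.ndarray] = None,
) -> PKProfile:
    """Perfusion-limited full PBPK simulation with a supplied Kp set.

    ``kp_set`` maps tissue name to tissue:plasma partition coefficient
    (the compound's ``kp_scalar`` is applied on top).  With no Kp set the
    engine falls back to the minimal model (logged).  Liver is the
    clearing tissue: elimination operates on the liver outflow blood
    concentration with the liver intrinsic clearance of ``pc`` (plus a
    kidney term), so dose/AUC matches the well-stirred algebra.
    """
    if kp_set is None:
        logger.info("%s: no Kp set supplied; falling back to minimal PBPK", compound.name)
        return simulate_minimal(compound, phys, pc, regimen, tgrid)
    missing = set(FULL_MODEL_TISSUES) - set(kp_set)
    if missing:
        raise ValueError(f"Kp set missing tissues: {sorted(missing)}")

    bw = phys.body_weight
    bp = pc.bp
    fu_b = pc.fu_b
    scalar = compound.distribution.kp_scalar
    kp = {t: max(kp_set[t] * scalar, 1e-9) for t in FULL_MODEL_TISSUES}
    vols = {t: FULL_MODEL_TISSUES[t]["volume"] * bw for t in FULL_MODEL_TISSUES}
    flows = {t: FULL_MODEL_TISSUES[t]["flow"] for t in FULL_MODEL_TISSUES}
    q_co = sum(flows.values())
    v_blood = BLOOD_VOLUME_L_PER_KG * bw
    v_ven = v_blood * VENOUS_FRACTION
    v_art = v_blood - v_ven

    # plasma-referenced: amount at distributional steady state per unit Cp
    vss_impl_p = v_blood * bp + sum(vols[t] * kp[t] for t in vols)
    if abs(vss_impl_p - compound.distribution.vss * bw) > 0.15 * compound.distribution.vss * bw:
        warnings.warn(
            f"{compound.name}: Kp-implied Vss {vss_impl_p / bw:.3g} L/kg deviates "
            f">15% from compound Vss {compound.distribution.vss:.3g} L/kg",
            stacklevel=2,
        )

    # liver/kidney metabolic intrinsic clearances (blood-unbound basis)
    clint_liver = pc.clint_liver_total
    clint_kidney = pc.clint_kidney_total
    cl_excret_b = (pc.cl_renal_excretion + pc.cl_biliary) / bp  # from venous blood

    oral = regimen.route == "oral"
    if oral:
        if compound.fa is None or compound.ka is None:
            raise ValueError(f"{compound.name}: oral simulation needs fa and ka")
        first_pass = pc.fg * pc.fh
        ka = compound.ka
    else:
        first_pass, ka = 1.0, 0.0

    if tgrid is None:
        tgrid = _default_tgrid(regimen, max(pc.cl_total_plasma, 1e-6),
                               compound.distribution.vss * bw)

    names = list(FULL_MODEL_TISSUES)
    # state: depot, venous amt, arterial amt, tissues..., eliminated
    n_t = len(names)

    def rhs_factory(rate):
        def rhs(t, y):
            a_dep = y[0]
            c_ven = y[1] / v_ven
            c_art = y[2] / v_art
            c_tis = y[3:3 + n_t] / np.array([vols[t_] for t_ in names])
            dy = np.zeros_like(y)
            dy[0] = -ka * a_dep
            inflow = ka * a_dep * first_pass + rate
            ven_in = 0.0
            elim = 0.0
            for i, t_ in enumerate(names):
                c_out = c_tis[i] * bp / kp[t_]  # emergent venous blood conc
                dy[3 + i] = flows[t_] * (c_art - c_out)
                if t_ == "liver" and clint_liver > 0:
                    met = fu_b * clint_liver * c_out
                    dy[3 + i] -= met
                    elim += met
                if t_ == "kidney" and clint_kidney > 0:
                    met = fu_b * clint_kidney * c_out
                    dy[3 + i] -= met
                    elim += met
                ven_in += flows[t_] * c_out
            excret = cl_excret_b * c_ven
            dy[1] = ven_in - q_co * c_ven + inflow - excret
            dy[2] = q_co * (c_ven - c_art)
            dy[-1] = elim + excret
            return dy

        return rhs

    def apply_instant(y, kind, value):
        y = y.copy()
        if kind == "depot":
            y[0] += compound.fa * value
        elif kind == "bolus":
            y[1] += value
        return y

    events = _dose_events(regimen, compound.t_lag if oral else 0.0)
    y0 = np.zeros(3 + n_t + 1)
    y = _integrate_events(rhs_factory, y0, events, tgrid, apply_instant)
    total_dose = regimen.dose * regimen.n_doses
    dose_sys = total_dose * (compound.fa * first_pass if oral else 1.0)
    conc_plasma = (y[1] / v_ven) / bp
    amounts = {"depot": y[0], "venous": y[1], "arterial": y[2], "eliminated": y[-1]}
    for i, t_ in enumerate(names):
        amounts[t_] = y[3 + i]
    return PKProfile(
        times=np.asarray(tgrid),
        conc=conc_plasma,
        regimen=regimen,
        compound_name=compound.name,
        amounts=amounts,
        dose_to_system=dose_sys,
    )


# ---------------------------------------------------------------------------
# non-compartmental metrics


def _auc_lin_log(t: np.ndarray, c: np.ndarray) -> float:
    """Linear-up/log-down trapezoidal AUC."""
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c0, c1 = c[i], c[i + 1]
        if c1 < c0 and c1 > 0 and c0 > 0:
            auc += dt * (c0 - c1) / math.log(c0 / c1)
        else:
            auc += dt * 0.5 * (c0 + c1)
    return auc


def pk_metrics(profile: PKProfile, n_terminal: int = 3) -> PKMetrics:
    """Non-compartmental metrics from a concentration-time profile.

    The terminal slope is a log-linear regression over the last
    ``n_terminal`` (>=3) positive concentrations;
    ``AUC_inf = AUC_t + C_last/lambda_z``.  CL (or CL/F for oral dosing)
    is ``dose_total/AUC_inf``.
    """
    t, c = profile.times, profile.conc
    if len(t) < 3:
        raise ValueError("at least 3 time points required")
    if n_terminal < 3:
        raise ValueError("terminal regression needs >= 3 points")
    auc_t = _auc_lin_log(t, c)
    cmax, tmax = profile.cmax, profile.tmax

    pos = c > 0
    idx = np.where(pos)[0]
    lam = t_half = auc_inf = cl = None
    if len(idx) >= n_terminal:
        tail = idx[-n_terminal:]
        slope, _ = np.polyfit(t[tail], np.log(c[tail]), 1)
        if slope < 0:
            lam = -slope
            t_half = math.log(2.0) / lam
            auc_inf = auc_t + c[idx[-1]] / lam
            total_dose = profile.regimen.dose * profile.regimen.n_doses
            cl = total_dose / auc_inf
        else:
            raise ExtrapolationError(
                "terminal phase is not declining; AUC_inf unavailable",
                auc_t=auc_t,
            )
    else:
        raise ExtrapolationError("too few positive terminal points", auc_t=auc_t)
    return PKMetrics(
        cmax=cmax, tmax=tmax, auc_t=auc_t, auc_inf=auc_inf,
        lambda_z=lam, t_half=t_half, cl_or_clf=cl,
    )
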