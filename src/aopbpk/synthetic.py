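"""Synthetic "observed" data generators.

These stand in for the clinical datasets the middle-out/top-down stages
normally consume: noisy plasma concentration-time profiles from known PK
parameters, mass-balance pathway-fraction tables with uncertainty
envelopes, and end-to-end parameter-recovery experiments.  Between-subject
variability is lognormal on clearance and Vss only, and residual error is
proportional lognormal — the standard minimal error model for
concentration assays.  Real clinical data have richer structure
(covariates, BLQ censoring, dropout) deliberately not emulated here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .clearance import predict_systemic, retrograde_clint
from .compounds import CompoundRecord, DoseRegimen, FmObserved
from .ivive import PathwayClearances
from .pbpk import PKProfile, simulate_minimal
from .physiology import SystemPhysiology, default_physiology, lognormal_sigma


@dataclass
class SyntheticStudy:
    """Design of a simulated clinical PK study."""

    compound: CompoundRecord
    pc: PathwayClearances  # generating truth
    regimen: DoseRegimen
    n_subjects: int
    times: np.ndarray  # sampling times, h
    cl_cv: float = 0.0  # % between-subject CV on clearance
    vss_cv: float = 0.0  # % between-subject CV on Vss
    residual_cv: float = 0.0  # % proportional residual CV
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("cl_cv", "vss_cv", "residual_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        self.times = np.asarray(self.times, dtype=float)


@dataclass
class SyntheticProfiles:
    profiles: list[PKProfile]
    cl_true: np.ndarray  # per-subject true plasma clearance, L/h
    vss_true: np.ndarray  # per-subject Vss, L/kg


def _scaled_pc(
    pc: PathwayClearances, cl_multiplier: float, phys: SystemPhysiology
) -> PathwayClearances:
    """Pathway network whose total systemic clearance is the truth scaled
    by ``cl_multiplier`` (excretory routes scale directly; intrinsic
    clearances are solved through the well-stirred nonlinearity)."""
    target_met = (pc.cl_total_plasma - pc.cl_renal_excretion - pc.cl_biliary) * cl_multiplier

    def build(s: float) -> PathwayClearances:
        return PathwayClearances(
            compound=pc.compound,
            clint_liver={p: v * s for p, v in pc.clint_liver.items()},
            clint_kidney={p: v * s for p, v in pc.clint_kidney.items()},
            cl_renal_excretion=pc.cl_renal_excretion * cl_multiplier,
            cl_biliary=pc.cl_biliary * cl_multiplier,
            bp=pc.bp,
            provenance=pc.provenance,
        )

    def objective(s: float) -> float:
        cand = build(s)
        predict_systemic(cand, phys)
        met = cand.cl_total_plasma - cand.cl_renal_excretion - cand.cl_biliary
        return met - target_met

    if target_met <= 0:
        new = build(0.0)
    else:
        hi = max(cl_multiplier, 1.0)
        while objective(hi) < 0:
            hi *= 4.0
            if hi > 1e12:
                raise ValueError("clearance multiplier beyond the flow limit")
        s = brentq(objective, 0.0, hi, rtol=1e-12, maxiter=200)
        new = build(s)
    predict_systemic(new, phys)
    return new


def synth_profiles(
    study: SyntheticStudy, phys: Optional[SystemPhysiology] = None
) -> SyntheticProfiles:
    """Simulate per-subject profiles with between-subject variability and
    proportional residual error; deterministic under the study seed."""
    phys = phys or default_physiology()
    rng = np.random.default_rng(study.seed)
    n = study.n_subjects
    sig_cl = lognormal_sigma(study.cl_cv)
    sig_v = lognormal_sigma(study.vss_cv)
    sig_e = lognormal_sigma(study.residual_cv)
    m_cl = rng.lognormal(-0.5 * sig_cl**2, sig_cl, n) if sig_cl > 0 else np.ones(n)
    m_v = rng.lognormal(-0.5 * sig_v**2, sig_v, n) if sig_v > 0 else np.ones(n)

    profiles = []
    cl_true = np.empty(n)
    vss_true = np.empty(n)
    for i in range(n):
        pc_i = _scaled_pc(study.pc, float(m_cl[i]), phys)
        cl_true[i] = pc_i.cl_total_plasma
        compound_i = study.compound.model_copy(deep=True)
        compound_i.distribution.vss = study.compound.distribution.vss * float(m_v[i])
        compound_i.distribution.vsac = study.compound.distribution.vsac * float(m_v[i])
        vss_true[i] = compound_i.distribution.vss
        prof = simulate_minimal(compound_i, phys, pc_i, study.regimen, tgrid=study.times)
        conc = prof.conc.copy()
        if sig_e > 0:
            conc *= rng.lognormal(-0.5 * sig_e**2, sig_e, size=conc.shape)
        profiles.append(
            PKProfile(
                times=prof.times, conc=conc, regimen=study.regimen,
                compound_name=study.compound.name,
            )
        )
    return SyntheticProfiles(profiles=profiles, cl_true=cl_true, vss_true=vss_true)


def synth_mass_balance(
    fm_true: dict[str, float], uncertainty: float, n: int, seed: int
) -> FmObserved:
    """Simulate replicate mass-balance fraction tables.

    Each replicate perturbs the true fractions with lognormal noise of
    shape ``uncertainty`` and renormalizes onto the simplex; the output
    carries the replicate mean and the min/max envelope.
    """
    total = sum(fm_true.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"fm_true must sum to 1, got {total:.6f}")
    if uncertainty < 0:
        raise ValueError("uncertainty must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    keys = list(fm_true)
    truth = np.array([fm_true[k] for k in keys])
    if uncertainty == 0:
        return FmObserved(
            mean=dict(fm_true), minimum=dict(fm_true), maximum=dict(fm_true)
        )
    rng = np.random.default_rng(seed)
    reps = truth * rng.lognormal(0.0, uncertainty, size=(n, len(keys)))
    reps /= reps.sum(axis=1, keepdims=True)
    return FmObserved(
        mean={k: float(v) for k, v in zip(keys, reps.mean(axis=0))},
        minimum={k: float(v) for k, v in zip(keys, reps.min(axis=0))},
        maximum={k: float(v) for k, v in zip(keys, reps.max(axis=0))},
    )


@dataclass
class RecoveryReport:
    clint_true: float
    clint_recovered: float
    clint_rel_error: float
    fm_true: dict[str, float]
    fm_envelope: FmObserved
    fm_in_envelope: bool
    cl_estimate: float
    cl_true: float


def _random_compound(rng: np.random.Generator) -> CompoundRecord:
    """A random but pharmacologically plausible iv-dosed test article."""
    vss = float(rng.uniform(0.5, 2.0))
    return CompoundRecord.model_validate(
        {
            "name": "synthetic-compound",
            "mw": float(rng.uniform(250, 500)),
            "ionization": "neutral",
            "logp": float(rng.uniform(0.5, 4.0)),
            "fu_p": float(rng.uniform(0.1, 0.9)),
            "bp": {"points": [[None, float(rng.uniform(0.7, 1.3))]]},
            "distribution": {
                "model": "minimal",
                "vss": vss,
                "vsac": 0.15 * vss,
                "q_intercompartment": 5.0,
            },
            "clint_entries": [
                {
                    "system": "HLC",
                    "pathway": "AO",
                    "value": float(rng.uniform(1.0, 8.0)),
                    "fu_inc": float(rng.uniform(0.4, 1.0)),
                },
                {
                    "system": "HLM",
                    "pathway": "nonAO",
                    "value": float(rng.uniform(1.0, 10.0)),
                    "fu_inc": float(rng.uniform(0.4, 1.0)),
                },
            ],
            "regimen": {"route": "iv-bolus", "dose": 10.0},
        }
    )


def recovery_experiment(
    seed: int,
    n_subjects: int = 24,
    residual_cv: float = 20.0,
    cl_cv: float = 0.0,
    fm_uncertainty: float = 0.1,
    phys: Optional[SystemPhysiology] = None,
) -> RecoveryReport:
    """End-to-end check of the middle-out machinery on synthetic truth.

    Generates a random plausible compound, simulates a PK study and a
    mass-balance experiment from its bottom-up model, estimates clearance
    non-compartmentally (geometric mean of per-subject dose/AUC_inf),
    back-calculates CLint,u, and reports recovery errors.
    """
    from .ivive import ESFPolicy, assemble_pathways

    phys = phys or default_physiology()
    rng = np.random.default_rng(seed)
    compound = _random_compound(rng)
    pc = assemble_pathways(compound, phys, source="HLM+HLC", esf=ESFPolicy())

    t_half = math.log(2.0) * compound.distribution.vss * phys.body_weight / pc.cl_total_plasma
    times = np.linspace(0.0, 16.0 * t_half, 321)
    study = SyntheticStudy(
        compound=compound,
        pc=pc,
        regimen=compound.regimen,
        n_subjects=n_subjects,
        times=times,
        cl_cv=cl_cv,
        residual_cv=residual_cv,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    sp = synth_profiles(study, phys)
    # a wide terminal window stabilizes lambda_z against residual noise
    cls = np.array([p.metrics(n_terminal=80).cl_or_clf for p in sp.profiles])
    cl_est = float(np.exp(np.mean(np.log(cls))))

    fm_true = pc.metabolic_fm()
    fm_true_paths: dict[str, float] = {}
    for key, v in fm_true.items():
        path = key.split(":")[0]
        fm_true_paths[path] = fm_true_paths.get(path, 0.0) + v
    envelope = synth_mass_balance(
        fm_true_paths, fm_uncertainty, n=max(6, n_subjects // 4),
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    res = retrograde_clint(
        cl_est, "iv", compound, phys, fm={k: envelope.mean[k] for k in envelope.mean}
    )
    clint_true = pc.clint_liver_total
    rel = abs(res.clint_liver_total - clint_true) / clint_true
    in_env = all(
        envelope.minimum[k] - 1e-12 <= fm_true_paths[k] <= envelope.maximum[k] + 1e-12
        for k in fm_true_paths
    )
    return RecoveryReport(
        clint_true=clint_true,
        clint_recovered=res.clint_liver_total,
        clint_rel_error=rel,
        fm_true=fm_true_paths,
        fm_envelope=envelope,
        fm_in_envelope=in_env,
        cl_estimate=cl_est,
        cl_true=pc.cl_total_plasma,
    )
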