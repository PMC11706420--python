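"""PBPK engine: closed-form limits, mass balance and engine/algebra consistency."""

import numpy as np
import pytest

import aopbpk as a
from aopbpk.compounds import CompoundRecord, DoseRegimen
from aopbpk.ivive import PATH_AO
from aopbpk.pbpk import ExtrapolationError


def _probe(vss=1.0, vsac=0.0, q=0.0, fu_p=0.5, bp=1.0, fa=0.9, ka=1.5):
    return CompoundRecord.model_validate(
        {
            "name": "probe", "mw": 350.0, "ionization": "neutral", "logp": 2.0,
            "fu_p": fu_p, "bp": {"points": [[None, bp]]},
            "fa": fa, "ka": ka, "qgut": 12.0,
            "distribution": {"model": "minimal", "vss": vss, "vsac": vsac,
                             "q_intercompartment": q},
        }
    )


def _network(compound, clint=300.0, phys=None):
    phys = phys or a.default_physiology()
    pc = a.PathwayClearances(
        compound=compound, clint_liver={PATH_AO: clint}, bp=compound.bp.at(),
    )
    a.predict_systemic(pc, phys)
    return pc


class TestMinimal:
    def test_iv_bolus_monoexponential(self, phys):
        c = _probe(vss=1.0, vsac=0.0)
        pc = _network(c, clint=100.0, phys=phys)
        cl = pc.cl_total_plasma
        v = 1.0 * phys.body_weight
        t = np.linspace(0, 24, 200)
        prof = a.simulate_minimal(c, phys, pc,
                                  DoseRegimen(route="iv-bolus", dose=100.0), tgrid=t)
        analytic = 100.0 / v * np.exp(-cl * t / v)
        mask = analytic > analytic[0] * 1e-6
        assert np.allclose(prof.conc[mask], analytic[mask], rtol=1e-6)

    def test_oral_mass_balance(self, phys):
        c = _probe(vss=1.0, vsac=0.3, q=2.0)
        pc = _network(c, phys=phys)
        prof = a.simulate_minimal(c, phys, pc, DoseRegimen(route="oral", dose=50.0))
        am = prof.amounts
        first_pass = pc.fg * pc.fh
        recovered = am["eliminated"][-1] + am["central"][-1] + am["sac"][-1] \
            + am["depot"][-1] * first_pass
        assert recovered == pytest.approx(c.fa * 50.0 * first_pass, rel=1e-6)

    def test_iv_mass_balance_at_every_time(self, phys):
        c = _probe()
        pc = _network(c, phys=phys)
        prof = a.simulate_minimal(
            c, phys, pc, DoseRegimen(route="iv-infusion", dose=80.0, infusion_duration=1.0),
            tgrid=np.linspace(0, 24, 100),
        )
        am = prof.amounts
        infused = np.minimum(prof.times, 1.0) * 80.0
        total = am["central"] + am["sac"] + am["eliminated"]
        assert np.allclose(total, infused, rtol=1e-6, atol=1e-6)

    def test_dose_proportionality(self, phys):
        c = _probe(vsac=0.2, q=1.0)
        pc = _network(c, phys=phys)
        t = np.linspace(0, 48, 100)
        p1 = a.simulate_minimal(c, phys, pc, DoseRegimen(route="oral", dose=10.0), tgrid=t)
        p2 = a.simulate_minimal(c, phys, pc, DoseRegimen(route="oral", dose=20.0), tgrid=t)
        mask = p1.conc > p1.cmax * 1e-9
        assert np.allclose(p2.conc[mask] / p1.conc[mask], 2.0, rtol=1e-7)
        assert p2.metrics().auc_inf == pytest.approx(2 * p1.metrics().auc_inf, rel=1e-7)

    def test_zaleplon_engine_matches_algebra(self, drugs, phys, bottom_up):
        z = drugs["zaleplon"]
        pc = bottom_up["zaleplon"]
        prof = a.simulate_minimal(z, phys, pc, z.regimen)
        cl_prof = prof.metrics().cl_or_clf
        assert cl_prof == pytest.approx(pc.cl_total_plasma, rel=0.01)

    def test_lag_time_delays_absorption(self, drugs, phys, bottom_up):
        zp = drugs["ziprasidone"]  # 4 h absorption lag
        t = np.linspace(0, 48, 400)
        prof = a.simulate_minimal(zp, phys, bottom_up["ziprasidone"],
                                  DoseRegimen(route="oral", dose=20.0), tgrid=t)
        assert prof.conc[t < 4.0].max() == 0.0
        assert prof.conc[t > 5.0].max() > 0.0

    def test_multiple_dose_accumulation(self, phys):
        c = _probe()
        pc = _network(c, clint=50.0, phys=phys)
        t = np.linspace(0, 96, 400)
        single = a.simulate_minimal(c, phys, pc, DoseRegimen(route="oral", dose=10.0), tgrid=t)
        multi = a.simulate_minimal(
            c, phys, pc,
            DoseRegimen(route="oral", dose=10.0, n_doses=4, interval=24.0), tgrid=t,
        )
        assert multi.conc[-1] > single.conc[-1]


class TestFull:
    def test_uniform_kp_no_elimination_equilibrates(self, phys):
        c = _probe(vss=1.0)
        pc = a.PathwayClearances(compound=c, clint_liver={PATH_AO: 0.0}, bp=1.0)
        a.predict_systemic(pc, phys)
        kp = {t: 1.0 for t in ("adipose", "muscle", "liver", "kidney", "rest")}
        tgrid = np.linspace(0, 400, 200)
        prof = a.simulate_full(c, phys, pc, kp, DoseRegimen(route="iv-bolus", dose=70.0),
                               tgrid=tgrid)
        am = prof.amounts
        from aopbpk.pbpk import FULL_MODEL_TISSUES
        c_end = {t: am[t][-1] / (FULL_MODEL_TISSUES[t]["volume"] * phys.body_weight)
                 for t in FULL_MODEL_TISSUES}
        vals = list(c_end.values())
        assert max(vals) == pytest.approx(min(vals), rel=1e-4)

    def test_ziprasidone_full_vs_algebra(self, drugs, phys, bottom_up):
        zp = drugs["ziprasidone"]
        pc = bottom_up["ziprasidone"]
        kp = a.uniform_kp_for_vss(zp, phys, pc.bp)
        prof = a.simulate_full(zp, phys, pc, kp, zp.regimen,
                               tgrid=np.linspace(0, 72, 600))
        assert prof.metrics().cl_or_clf == pytest.approx(pc.cl_total_plasma, rel=0.05)

    def test_minimal_and_full_agree_on_auc(self, phys):
        c = _probe(vss=1.2, vsac=0.3, q=2.0)
        pc = _network(c, clint=200.0, phys=phys)
        kp = a.uniform_kp_for_vss(c, phys, pc.bp)
        # infuse over 0.5 h: an instantaneous venous bolus creates a
        # sub-grid mixing spike that the trapezoid cannot resolve
        reg = DoseRegimen(route="iv-infusion", dose=100.0, infusion_duration=0.5)
        t = np.linspace(0, 60, 2401)
        auc_min = a.simulate_minimal(c, phys, pc, reg, tgrid=t).metrics().auc_inf
        auc_full = a.simulate_full(c, phys, pc, kp, reg, tgrid=t).metrics().auc_inf
        assert auc_full == pytest.approx(auc_min, rel=0.01)

    def test_vss_mismatch_warns(self, phys):
        c = _probe(vss=0.3)  # all-Kp=1 implies 1.0 L/kg, >> 0.3
        pc = _network(c, clint=100.0, phys=phys)
        kp = {t: 1.0 for t in ("adipose", "muscle", "liver", "kidney", "rest")}
        with pytest.warns(UserWarning, match="Vss"):
            a.simulate_full(c, phys, pc, kp, DoseRegimen(route="iv-bolus", dose=10.0),
                            tgrid=np.linspace(0, 24, 50))

    def test_missing_kp_falls_back_to_minimal(self, phys):
        c = _probe()
        pc = _network(c, phys=phys)
        reg = DoseRegimen(route="iv-bolus", dose=10.0)
        t = np.linspace(0, 24, 50)
        pf = a.simulate_full(c, phys, pc, None, reg, tgrid=t)
        pm = a.simulate_minimal(c, phys, pc, reg, tgrid=t)
        assert np.allclose(pf.conc, pm.conc)


class TestMetrics:
    def test_monoexponential_auc_exact(self):
        lam, c0 = 0.2, 5.0
        t = np.linspace(0, 40, 300)
        prof = a.PKProfile(times=t, conc=c0 * np.exp(-lam * t),
                           regimen=DoseRegimen(route="iv-bolus", dose=1.0))
        m = prof.metrics()
        assert m.auc_inf == pytest.approx(c0 / lam, rel=1e-9)
        assert m.t_half == pytest.approx(np.log(2) / lam, rel=1e-9)

    def test_too_few_points_rejected(self):
        prof = a.PKProfile(times=np.array([0.0, 1.0]), conc=np.array([1.0, 0.5]),
                           regimen=DoseRegimen(route="iv-bolus", dose=1.0))
        with pytest.raises(ValueError):
            prof.metrics()

    def test_non_monotone_terminal_raises_with_auc(self):
        t = np.linspace(0, 10, 11)
        conc = np.ones_like(t)  # flat: no terminal decline
        prof = a.PKProfile(times=t, conc=conc,
                           regimen=DoseRegimen(route="iv-bolus", dose=1.0))
        with pytest.raises(ExtrapolationError) as exc:
            prof.metrics()
        assert exc.value.auc_t == pytest.approx(10.0)

    def test_simulated_iv_cl_round_trip(self, drugs, phys, bottom_up):
        zp = drugs["zoniporide"]
        pc = bottom_up["zoniporide"]
        prof = a.simulate_minimal(zp, phys, pc, zp.regimen)
        assert prof.metrics().cl_or_clf == pytest.approx(pc.cl_total_plasma, rel=0.01)
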