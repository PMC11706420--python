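"""Well-stirred organ algebra, gut availability and retrograde inversion."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aopbpk as a
from aopbpk.clearance import InfeasibleClearanceError
from aopbpk.compounds import CompoundRecord
from aopbpk.ivive import PATH_AO, PATH_CYP3A4


class TestWellStirred:
    def test_worked_example(self):
        assert a.well_stirred_cl(87, 0.335, 1426) == pytest.approx(73.6, rel=1e-3)

    def test_restrictive_limit(self):
        # low CLint: CL -> fu_B * CLint
        assert a.well_stirred_cl(100, 0.1, 0.01) == pytest.approx(0.001, rel=1e-4)

    def test_flow_limit(self):
        assert a.well_stirred_cl(87, 0.5, 1e12) == pytest.approx(87, rel=1e-6)

    @given(
        q=st.floats(min_value=10, max_value=200),
        fub=st.floats(min_value=1e-3, max_value=2.0),
        cl=st.floats(min_value=0.0, max_value=1e5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounded_by_flow_and_unbound_clint(self, q, fub, cl):
        out = a.well_stirred_cl(q, fub, cl)
        assert out <= min(q, fub * cl) + 1e-12
        assert a.well_stirred_cl(q, fub, cl + 1.0) > out  # strictly monotone


class TestHepaticAvailability:
    def test_no_metabolism_full_availability(self):
        assert a.hepatic_availability(87, 0.335, 0.0) == 1.0

    def test_worked_example(self):
        assert a.hepatic_availability(87, 0.335, 1426) == pytest.approx(0.154, abs=1e-3)

    def test_complement_of_extraction(self):
        q, fub, cl = 97.0, 0.05, 3000.0
        e_h = a.well_stirred_cl(q, fub, cl) / q
        assert a.hepatic_availability(q, fub, cl) + e_h == pytest.approx(1.0, rel=1e-12)


class TestQgutFg:
    def test_no_gut_metabolism(self):
        assert a.qgut_fg(10.0, 0.5, 0.0) == 1.0

    def test_ziprasidone_example(self):
        # gut CLint = 1% of hepatic CYP3A4 CLint,u (~3796 L/h with ESF)
        assert a.qgut_fg(6.21, 0.0029, 37.96) == pytest.approx(0.983, abs=1e-3)

    def test_idelalisib_high_fg(self, bottom_up):
        assert bottom_up["idelalisib"].fg >= 0.99

    @given(cl=st.floats(min_value=0.0, max_value=1e4))
    @settings(max_examples=50, derandomize=True)
    def test_fg_in_unit_interval_and_decreasing(self, cl):
        fg = a.qgut_fg(12.0, 0.1, cl)
        assert 0.0 < fg <= 1.0
        assert a.qgut_fg(12.0, 0.1, cl + 1.0) < fg


class TestPredictSystemic:
    def test_zaleplon_iv_clearance_near_observed(self, bottom_up):
        cl = bottom_up["zaleplon"].cl_total_plasma
        assert 50.0 <= cl <= 58.0  # observed 52.5 (f) / 71.6 (m) L/h

    def test_zero_pathways_zero_clearance(self, drugs, phys):
        pc = a.PathwayClearances(
            compound=drugs["zaleplon"], clint_liver={PATH_AO: 0.0}, bp=0.91,
        )
        out = a.predict_systemic(pc, phys)
        assert out["cl_iv"] == 0.0
        with pytest.raises(ValueError):
            a.compute_fm(pc)  # fm undefined at zero clearance

    def test_oral_over_f_exceeds_iv(self, bottom_up):
        pc = bottom_up["capmatinib"]
        out = a.predict_systemic(pc, a.default_physiology())
        assert out["cl_over_f"] > out["cl_iv"]
        assert 0 < out["f"] < 1


def _simple_compound(fu_p=0.2, bp=1.0, fa=0.9, renal=0.0):
    return CompoundRecord.model_validate(
        {
            "name": "probe", "mw": 350.0, "ionization": "neutral", "logp": 2.0,
            "fu_p": fu_p, "bp": {"points": [[None, bp]]},
            "fa": fa, "ka": 1.5, "qgut": 12.0,
            "distribution": {"model": "minimal", "vss": 1.0, "vsac": 0.2,
                             "q_intercompartment": 1.0},
            "cl_renal_obs": renal,
        }
    )


class TestRetrograde:
    def test_oral_hepatic_only_closed_form(self, phys):
        # with a single hepatic pathway CL/F = fu_p*CLint,u/(fa*Fg);
        # AO-only metabolism leaves no gut CYP3A4, so Fg = 1
        c = _simple_compound(fu_p=0.0536, fa=0.965)
        res = a.retrograde_clint(15.3, "oral", c, phys, fm={PATH_AO: 1.0},
                                 include_kidney_ao=False)
        assert res.clint_liver_total == pytest.approx(15.3 * 0.965 / 0.0536, rel=1e-8)

    def test_iv_inversion_closed_form(self, phys):
        c = _simple_compound(fu_p=0.5, bp=1.0)
        cl_obs = 20.0
        res = a.retrograde_clint(cl_obs, "iv", c, phys, fm={PATH_AO: 1.0},
                                 include_kidney_ao=False)
        q = phys.hepatic_blood_flow
        expected = q * cl_obs / (0.5 * (q - cl_obs))
        assert res.clint_liver_total == pytest.approx(expected, rel=1e-8)

    def test_iv_above_flow_limit_infeasible(self, phys):
        c = _simple_compound()
        with pytest.raises(InfeasibleClearanceError, match="flow"):
            a.retrograde_clint(200.0, "iv", c, phys, include_kidney_ao=False)

    def test_zoniporide_kidney_ao_relieves_flow_limit(self, drugs, phys):
        z = drugs["zoniporide"]
        res = a.retrograde_clint(z.cl_obs.summary, "iv", z, phys, fm={PATH_AO: 1.0})
        pc = res.pathway_clearances
        met = pc.metabolic_fm()
        kidney_share = met.get(f"{PATH_AO}:kidney", 0.0)
        assert 0.0 < kidney_share <= 0.18
        assert pc.cl_total_plasma == pytest.approx(z.cl_obs.summary, rel=1e-6)

    @given(
        fu_p=st.floats(min_value=0.01, max_value=0.9),
        bp=st.floats(min_value=0.6, max_value=2.0),
        clint_ao=st.floats(min_value=10.0, max_value=3000.0),
        clint_cyp=st.floats(min_value=0.0, max_value=3000.0),
        renal=st.floats(min_value=0.0, max_value=5.0),
        route_oral=st.booleans(),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_forward_then_retrograde_identity(
        self, phys, fu_p, bp, clint_ao, clint_cyp, renal, route_oral
    ):
        """Inverting the forward prediction recovers CLint,u to 1e-6."""
        c = _simple_compound(fu_p=fu_p, bp=bp, renal=renal)
        pc = a.PathwayClearances(
            compound=c,
            clint_liver={PATH_AO: clint_ao, PATH_CYP3A4: clint_cyp},
            clint_kidney={PATH_AO: a.kidney_to_liver_ao_ratio(phys) * clint_ao},
            cl_renal_excretion=renal,
            bp=bp,
        )
        out = a.predict_systemic(pc, phys)
        total = pc.clint_liver_total
        fm_liver = {PATH_AO: clint_ao / total, PATH_CYP3A4: clint_cyp / total}
        cl = out["cl_over_f"] if route_oral else out["cl_iv"]
        res = a.retrograde_clint(
            cl, "oral" if route_oral else "iv", c, phys, fm=fm_liver
        )
        assert res.clint_liver_total == pytest.approx(total, rel=1e-6)

    def test_fm_split_proportional(self, phys):
        c = _simple_compound()
        res = a.retrograde_clint(10.0, "iv", c, phys,
                                 fm={PATH_AO: 0.6, PATH_CYP3A4: 0.4})
        assert res.clint_liver[PATH_AO] / res.clint_liver_total == pytest.approx(0.6)
        assert res.per_mg_cytosolic is not None and res.per_mg_microsomal is not None


class TestMiddleOutFm:
    def test_total_clint_and_cl_preserved(self, bottom_up, phys, drugs):
        pc = bottom_up["ziprasidone"]
        new = a.middle_out_fm(pc, {PATH_AO: 0.67, PATH_CYP3A4: 0.33}, phys)
        assert new.clint_liver_total == pytest.approx(pc.clint_liver_total, rel=1e-12)
        # same total CLint,u -> essentially unchanged total clearance
        assert new.cl_total_plasma == pytest.approx(pc.cl_total_plasma, rel=0.02)
        assert new.fm[PATH_AO] == pytest.approx(0.67, abs=0.02)
        assert new.provenance == "middle-out-fm"
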