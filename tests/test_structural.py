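"""Structural parent-metabolite model: closed form vs ODE, covariate model,
steady-state metrics and their analytic identities."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aripk.structural import (
    Regimen,
    StructuralParams,
    concentration_profile,
    individual_params,
    ode_states,
    steady_state_concentration,
    steady_state_metrics,
    ss_trough_arrays,
)

TYPICAL = dict(ka=1.06, vd_f=219.91, cl_f=3.06, vdm_fm=423.78, clm_fm=8.86)


@pytest.fixture(scope="module")
def typical():
    return StructuralParams(**TYPICAL)


class TestIndividualParams:
    def test_reference_typical_values_at_70kg_nm(self, ref_model):
        p = individual_params(ref_model.cov_model, 70.0, "NM")
        assert p.cl_f == pytest.approx(3.06)
        assert p.vd_f == pytest.approx(219.91)
        assert p.clm_fm == pytest.approx(8.86)
        assert p.vdm_fm == pytest.approx(423.78)
        assert p.ka == pytest.approx(1.06)

    def test_im_clearance_shift(self, ref_model):
        # additive log-scale genotype coefficient: a 20.55% decrease
        p = individual_params(ref_model.cov_model, 70.0, "IM")
        assert p.cl_f == pytest.approx(3.06 * math.exp(-0.23), rel=1e-12)
        assert p.cl_f == pytest.approx(2.4312, abs=2e-4)

    def test_allometric_clearance_at_36kg(self, ref_model):
        p = individual_params(ref_model.cov_model, 36.0, "NM")
        oracle = 3.06 * (36.0 / 70.0) ** 0.64
        assert p.cl_f == pytest.approx(oracle, rel=1e-12)
        assert oracle == pytest.approx(1.9994, abs=5e-5)

    def test_etas_scale_lognormally(self, ref_model):
        p = individual_params(ref_model.cov_model, 70.0, "NM",
                              etas={"cl_f": 0.5, "vd_f": -0.2})
        assert p.cl_f == pytest.approx(3.06 * math.exp(0.5))
        assert p.vd_f == pytest.approx(219.91 * math.exp(-0.2))

    def test_unknown_phenotype_raises(self, ref_model):
        with pytest.raises(ValueError, match="phenotype"):
            individual_params(ref_model.cov_model, 70.0, "XX")

    def test_pm_without_coefficient_raises(self, ref_model):
        with pytest.raises(KeyError, match="PM"):
            individual_params(ref_model.cov_model, 70.0, "PM")

    def test_nonpositive_weight_raises(self, ref_model):
        with pytest.raises(ValueError):
            individual_params(ref_model.cov_model, 0.0, "NM")


class TestConcentrationProfile:
    def test_zero_at_time_zero(self, typical):
        cp, cm = concentration_profile(typical, Regimen(dose=5.0), [0.0])
        assert cp[0] == 0.0 and cm[0] == 0.0

    def test_closed_form_matches_ode_single_dose(self, typical):
        t = np.array([1.0, 6.0, 24.0])
        reg = Regimen(dose=5.0)
        cp_c, cm_c = concentration_profile(typical, reg, t, method="closed")
        cp_o, cm_o = concentration_profile(typical, reg, t, method="ode")
        assert np.max(np.abs(cp_c - cp_o) / cp_o) < 1e-6
        assert np.max(np.abs(cm_c - cm_o) / cm_o) < 1e-6

    def test_closed_form_matches_ode_random_params(self):
        rng = np.random.default_rng(11)
        reg = Regimen(dose=10.0, tau=24.0, n_doses=8)
        t = np.array([3.0, 30.0, 100.0, 180.0])
        for _ in range(25):
            p = StructuralParams(
                ka=rng.uniform(0.3, 3.0),
                vd_f=rng.uniform(50, 600),
                cl_f=rng.uniform(0.5, 12),
                vdm_fm=rng.uniform(50, 1200),
                clm_fm=rng.uniform(1, 25),
            )
            cp_c, cm_c = concentration_profile(p, reg, t, method="closed")
            cp_o, cm_o = concentration_profile(p, reg, t, method="ode")
            assert np.max(np.abs(cp_c - cp_o) / np.abs(cp_o)) < 1e-6
            assert np.max(np.abs(cm_c - cm_o) / np.abs(cm_o)) < 1e-6

    def test_mass_balance_with_unit_scales(self):
        # with f = fm = kn = 1 the four amount states sum to the given dose
        p = StructuralParams(**{**TYPICAL, "kn": 1.0})
        states = ode_states(p, Regimen(dose=5.0, n_doses=2), np.array([5.0, 30.0]))
        np.testing.assert_allclose(states.sum(axis=1), [5.0, 10.0], rtol=1e-8)

    def test_dose_linearity(self, typical):
        t = np.array([4.0, 40.0])
        reg1 = Regimen(dose=5.0, n_doses=3)
        reg3 = Regimen(dose=15.0, n_doses=3)
        c1 = concentration_profile(typical, reg1, t)
        c3 = concentration_profile(typical, reg3, t)
        np.testing.assert_allclose(3 * np.array(c1), np.array(c3), rtol=1e-12)

    def test_degenerate_rate_constants_fall_back_to_ode(self):
        # ka exactly equal to ke: closed form would divide by zero
        p = StructuralParams(ka=0.5, vd_f=100.0, cl_f=50.0, vdm_fm=400.0,
                             clm_fm=8.0)
        assert p.degenerate
        cp, cm = concentration_profile(p, Regimen(dose=5.0), [2.0, 10.0])
        assert np.all(np.isfinite(cp)) and np.all(np.isfinite(cm))
        assert np.all(cp > 0) and np.all(cm > 0)

    def test_zero_dose_gives_zero_profile(self, typical):
        cp, cm = concentration_profile(typical, Regimen(dose=0.0), [1.0, 10.0])
        assert np.all(cp == 0) and np.all(cm == 0)

    def test_times_before_first_dose_are_zero(self, typical):
        reg = Regimen(dose=5.0, start_time=48.0)
        cp, cm = concentration_profile(typical, reg, [0.0, 47.0, 50.0])
        assert cp[0] == cp[1] == 0.0
        assert cp[2] > 0


class TestSteadyState:
    def test_auc_identities(self, typical):
        m = steady_state_metrics(typical, Regimen(dose=5.0))
        auc_ari = 5.0 / 3.06 * 1000.0
        auc_dari = 0.995 * 5.0 / 8.86 * 1000.0
        assert m.auc24_ari == pytest.approx(auc_ari, rel=1e-8)
        assert m.auc24_dari == pytest.approx(auc_dari, rel=1e-8)

    def test_typical_nm_metabolic_ratio(self, typical):
        m = steady_state_metrics(typical, Regimen(dose=5.0))
        assert m.mr_auc == pytest.approx(0.995 * 3.06 / 8.86, rel=1e-8)
        assert round(m.mr_auc, 2) == 0.34

    def test_trough_below_peak(self, typical):
        m = steady_state_metrics(typical, Regimen(dose=7.5))
        assert 0 < m.cmin_ari < m.cmax_ari
        assert 0 < m.cmin_dari < m.cmax_dari

    def test_zero_dose_flags_undefined_ratios(self, typical):
        m = steady_state_metrics(typical, Regimen(dose=0.0))
        assert m.auc24_ari == 0 and m.cmax_dari == 0
        assert math.isnan(m.mr_auc) and not m.defined

    def test_mr_is_dose_invariant(self, typical):
        m1 = steady_state_metrics(typical, Regimen(dose=2.5))
        m2 = steady_state_metrics(typical, Regimen(dose=20.0))
        assert m1.mr_auc == pytest.approx(m2.mr_auc, rel=1e-9)
        assert m1.mr_cmin == pytest.approx(m2.mr_cmin, rel=1e-7)

    def test_long_simulation_converges_to_analytic_steady_state(self, typical):
        reg = Regimen(dose=5.0, tau=24.0, n_doses=60)
        t = np.array([60 * 24.0 - 1e-6])
        cp, cm = concentration_profile(typical, reg, t)
        ssp, ssm = steady_state_concentration(typical, 5.0, 24.0, 24.0)
        assert cp[0] == pytest.approx(float(ssp), rel=1e-6)
        assert cm[0] == pytest.approx(float(ssm), rel=1e-6)

    def test_phenotype_trough_ordering(self, ref_model):
        # lower CYP2D6 activity means slower clearance and higher troughs
        troughs = {}
        for ph in ("IM", "NM", "UM"):
            p = individual_params(ref_model.cov_model, 36.0, ph)
            troughs[ph] = steady_state_metrics(p, Regimen(dose=5.0)).cmin_ari
        assert troughs["IM"] > troughs["NM"] > troughs["UM"]

    def test_vectorised_trough_matches_metrics(self, typical):
        ca, cd = ss_trough_arrays(3.06, 219.91, 8.86, 423.78, 5.0)
        m = steady_state_metrics(typical, Regimen(dose=5.0))
        assert float(ca) == pytest.approx(m.cmin_ari, rel=1e-9)
        assert float(cd) == pytest.approx(m.cmin_dari, rel=1e-9)

    def test_doubled_volumes_preserve_auc_and_damp_fluctuation(self, typical):
        doubled = StructuralParams(**{**TYPICAL, "vd_f": 2 * TYPICAL["vd_f"],
                                      "vdm_fm": 2 * TYPICAL["vdm_fm"]})
        m1 = steady_state_metrics(typical, Regimen(dose=5.0))
        m2 = steady_state_metrics(doubled, Regimen(dose=5.0))
        assert m2.auc24_ari == pytest.approx(m1.auc24_ari, rel=1e-8)
        fluct1 = (m1.cmax_ari - m1.cmin_ari) / m1.auc24_ari
        fluct2 = (m2.cmax_ari - m2.cmin_ari) / m2.auc24_ari
        assert fluct2 < fluct1


@given(
    dose=st.floats(1.0, 20.0),
    scale=st.floats(1.5, 4.0),
)
def test_scaling_dose_scales_all_metrics(dose, scale):
    p = StructuralParams(**TYPICAL)
    m1 = steady_state_metrics(p, Regimen(dose=dose))
    m2 = steady_state_metrics(p, Regimen(dose=dose * scale))
    assert m2.auc24_ari == pytest.approx(scale * m1.auc24_ari, rel=1e-8)
    assert m2.cmin_dari == pytest.approx(scale * m1.cmin_dari, rel=1e-8)
    assert m2.cmax_ari == pytest.approx(scale * m1.cmax_ari, rel=1e-5)


def test_invalid_parameters_and_regimens_raise():
    with pytest.raises(ValueError):
        StructuralParams(ka=1.0, vd_f=-1.0, cl_f=1.0, vdm_fm=1.0, clm_fm=1.0)
    with pytest.raises(ValueError):
        Regimen(dose=-1.0)
    with pytest.raises(ValueError):
        Regimen(dose=1.0, tau=0.0)
    with pytest.raises(ValueError):
        Regimen(dose=1.0, n_doses=0)
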