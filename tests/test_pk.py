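"""Structural kinetics: single dose, steady state, superposition, exposure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bdqpk.pk import (
    CovariateModel,
    PKParameters,
    Regimen,
    apply_covariates,
    conc_profile,
    conc_single_dose,
    conc_steady_state,
    exposure_metrics,
    tmax_steady_state,
)

from oracles import ode_concentration


class TestSingleDose:
    def test_zero_at_dose_time(self, typical_params):
        assert conc_single_dose(typical_params, 200.0, 0.0) == 0.0

    def test_matches_ode_oracle(self, typical_params):
        times = np.array([0.5, 2.0, 6.37, 24.0, 56.0, 168.0])
        closed = conc_single_dose(typical_params, 200.0, times)
        ode = ode_concentration(typical_params.ka, typical_params.cl, typical_params.v, 200.0, times)
        np.testing.assert_allclose(closed, ode, rtol=1e-3 * 0.1)

    @settings(max_examples=25, deadline=None)
    @given(
        ka=st.floats(0.05, 5.0),
        cl=st.floats(0.5, 20.0),
        v=st.floats(20.0, 500.0),
        t=st.floats(0.0, 168.0),
    )
    def test_ode_agreement_random_parameters(self, ka, cl, v, t):
        p = PKParameters(ka=ka, cl=cl, v=v)
        if p.is_degenerate():
            return
        closed = conc_single_dose(p, 150.0, t)
        ode = float(ode_concentration(ka, cl, v, 150.0, [t])[0])
        assert closed == pytest.approx(ode, rel=1e-3, abs=1e-9)

    def test_dose_linearity(self, typical_params):
        t = np.linspace(0.0, 100.0, 23)
        c1 = conc_single_dose(typical_params, 100.0, t)
        c2 = conc_single_dose(typical_params, 200.0, t)
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-12)

    def test_degenerate_rates_raise_unless_enabled(self):
        p = PKParameters(ka=0.1, cl=1.0, v=10.0)  # ke = 0.1 = ka
        with pytest.raises(ValueError, match="coincide"):
            conc_single_dose(p, 100.0, 5.0)
        limit = conc_single_dose(p, 100.0, 5.0, allow_equal_rates=True)
        near = conc_single_dose(PKParameters(0.1 + 1e-6, 1.0, 10.0), 100.0, 5.0)
        assert limit == pytest.approx(near, rel=1e-4)


class TestSteadyState:
    def test_trough_values_for_reference_strata(self):
        # typical A/AG subject at GGT 30 and GG subject at GGT 100
        for cl, expected in ((4.459, 0.460), (1.114, 2.815)):
            p = PKParameters(ka=0.447, cl=cl, v=227.0)
            assert conc_steady_state(p, 200.0, 56.0, 0.0) == pytest.approx(expected, rel=5e-3)

    def test_periodicity(self, typical_params):
        c0 = conc_steady_state(typical_params, 200.0, 56.0, 0.0)
        c1 = conc_steady_state(typical_params, 200.0, 56.0, 56.0)
        assert c0 == pytest.approx(c1, rel=1e-12)

    def test_superposition_converges_to_steady_state(self, typical_params):
        # 90 consecutive doses (30 weeks of thrice-weekly dosing)
        n = 90
        reg = Regimen.repeated(200.0, 56.0, n)
        t_in_last = np.linspace(0.0, 56.0, 15)
        prof = conc_profile(typical_params, reg, (n - 1) * 56.0 + t_in_last)
        ss = conc_steady_state(typical_params, 200.0, 56.0, t_in_last)
        np.testing.assert_allclose(prof, ss, rtol=1e-3)

    def test_steady_state_matches_ode_oracle(self, typical_params):
        times = np.array([1.0, 6.37, 28.0, 55.0])
        n = 90
        ode = ode_concentration(
            typical_params.ka, typical_params.cl, typical_params.v, 200.0, times, n_doses=n, tau=56.0
        )
        ss = conc_steady_state(typical_params, 200.0, 56.0, times)
        np.testing.assert_allclose(ss, ode, rtol=1e-3)

    def test_time_outside_interval_rejected(self, typical_params):
        with pytest.raises(ValueError):
            conc_steady_state(typical_params, 200.0, 56.0, 57.0)


class TestProfile:
    def test_single_dose_profile_equals_bateman(self, typical_params):
        t = np.linspace(0, 80, 17)
        np.testing.assert_allclose(
            conc_profile(typical_params, Regimen.single(200.0), t),
            conc_single_dose(typical_params, 200.0, t),
        )

    def test_empty_times(self, typical_params):
        assert conc_profile(typical_params, Regimen.single(200.0), []).size == 0

    def test_no_contribution_before_dose(self, typical_params):
        reg = Regimen.single(200.0, time=24.0)
        c = conc_profile(typical_params, reg, [0.0, 12.0, 23.9, 30.0])
        assert np.all(c[:3] == 0.0) and c[3] > 0


class TestCovariateModel:
    def test_reference_ggt_returns_base_clearance(self, final_cov_model):
        assert apply_covariates(final_cov_model, 28.9, False) == pytest.approx(4.54)

    @pytest.mark.parametrize(
        "ggt,gg,expected",
        [(10.0, False, 600.0 / 79.746), (100.0, True, 600.0 / 538.383)],
    )
    def test_derived_clearances_match_weekly_auc(self, final_cov_model, ggt, gg, expected):
        assert apply_covariates(final_cov_model, ggt, gg) == pytest.approx(expected, rel=5e-4)

    def test_monotone_decreasing_in_ggt_and_lower_for_gg(self, final_cov_model):
        ggts = np.linspace(8.0, 250.0, 40)
        cl_a = np.array([apply_covariates(final_cov_model, g, False) for g in ggts])
        assert np.all(np.diff(cl_a) < 0)
        for g in (10.0, 30.0, 100.0):
            assert apply_covariates(final_cov_model, g, True) < apply_covariates(final_cov_model, g, False)

    def test_nonpositive_clearance_raises(self):
        cm = CovariateModel()
        with pytest.raises(ValueError, match="non-positive"):
            # GG shift overwhelms the power term at extreme GGT
            apply_covariates(cm, 5e5, True)
        with pytest.raises(ValueError):
            apply_covariates(cm, -1.0, False)


class TestExposureMetrics:
    def test_reference_stratum_values(self):
        p = PKParameters(ka=0.447, cl=4.459, v=227.0)
        m = exposure_metrics(p, 200.0, 56.0)
        assert m.auc_weekly_ss == pytest.approx(134.529, rel=5e-3)
        assert m.cmax_ss == pytest.approx(1.165, rel=5e-3)
        assert m.cmin_ss == pytest.approx(0.460, rel=5e-3)

    def test_auc_halves_when_clearance_doubles(self, typical_params):
        m1 = exposure_metrics(typical_params, 200.0, 56.0)
        p2 = PKParameters(typical_params.ka, 2 * typical_params.cl, typical_params.v)
        m2 = exposure_metrics(p2, 200.0, 56.0)
        assert m2.auc_weekly_ss == pytest.approx(m1.auc_weekly_ss / 2, rel=1e-12)

    def test_analytic_auc_matches_trapezoid(self, typical_params):
        # one steady-state week at 1-minute resolution
        t = np.arange(0.0, 56.0 + 1e-9, 1.0 / 60.0)
        c = conc_steady_state(typical_params, 200.0, 56.0, t)
        auc_num = 3 * np.trapezoid(c, t)
        m = exposure_metrics(typical_params, 200.0, 56.0)
        assert m.auc_weekly_ss == pytest.approx(auc_num, rel=5e-3)

    def test_tmax_is_stationary_point(self, typical_params):
        tmax = tmax_steady_state(typical_params, 56.0)
        eps = 1e-4
        c0 = conc_steady_state(typical_params, 200.0, 56.0, tmax)
        assert c0 > conc_steady_state(typical_params, 200.0, 56.0, tmax - eps)
        assert c0 > conc_steady_state(typical_params, 200.0, 56.0, tmax + eps)

    def test_metrics_increase_with_ggt_and_for_gg(self, final_cov_model):
        rows = {}
        for gg in (False, True):
            for ggt in (10.0, 30.0, 50.0, 100.0):
                cl = apply_covariates(final_cov_model, ggt, gg)
                rows[(gg, ggt)] = exposure_metrics(PKParameters(0.447, cl, 227.0), 200.0, 56.0)
        for gg in (False, True):
            seq = [rows[(gg, g)] for g in (10.0, 30.0, 50.0, 100.0)]
            for a, b in zip(seq, seq[1:]):
                assert b.cmax_ss > a.cmax_ss and b.cmin_ss > a.cmin_ss and b.auc_weekly_ss > a.auc_weekly_ss
        for g in (10.0, 30.0, 50.0, 100.0):
            assert rows[(True, g)].auc_weekly_ss > rows[(False, g)].auc_weekly_ss


class TestValidation:
    @pytest.mark.parametrize("bad", [dict(ka=-1, cl=1, v=10), dict(ka=1, cl=0, v=10), dict(ka=1, cl=1, v=float("nan"))])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            PKParameters(**bad)

    def test_regimen_ordering_enforced(self):
        from bdqpk.pk import DoseEvent

        with pytest.raises(ValueError):
            Regimen((DoseEvent(200.0, 10.0), DoseEvent(200.0, 5.0)))
        with pytest.raises(ValueError):
            DoseEvent(200.0, 0.0, ss=True, tau=None)
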