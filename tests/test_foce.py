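"""Likelihood engine: conditional density, FOCE objective, fitting, diagnostics."""

import math

import numpy as np
import pytest

from bdqpk.data import Observation, SubjectRecord
from bdqpk.foce import _Engine, conditional_m2ll, diagnostics, fit, foce_objective
from bdqpk.model import CovariateEffect, PopulationModel, final_model
from bdqpk.pk import DoseEvent, PKParameters, conc_steady_state
from bdqpk.simulate import StudyDesignSpec, generate_dataset

from oracles import exact_marginal_m2ll

COV = {"GGT": 28.9, "RS319952_GG": 0.0}


def make_subject(times_concs, sid=1, cov=COV):
    return SubjectRecord(
        id=sid,
        doses=(DoseEvent(200.0, 0.0, ss=True, tau=56.0),),
        observations=tuple(Observation(t, c) for t, c in times_concs),
        covariates=dict(cov),
    )


def subject_at_prediction(times, rel_dev, m=None, cov=COV):
    """Subject whose observations sit at stated relative deviations from the
    typical steady-state prediction."""
    m = m or final_model()
    p = PKParameters(m.theta["ka"], 4.54, m.theta["v"])
    return make_subject(
        [(t, conc_steady_state(p, 200.0, 56.0, t) * (1.0 + d)) for t, d in zip(times, rel_dev)]
    )


class TestConditionalM2ll:
    def test_matches_direct_density_computation(self):
        m = final_model()
        rec = make_subject([(6.0, 1.2), (30.0, 0.7)])
        eta = np.array([0.2, -0.3])
        # independent arithmetic: SS concentration, proportional variance,
        # Gaussian log-density plus the eta prior
        cl = 4.54 * math.exp(eta[0])
        v = 227.0 * math.exp(eta[1])
        p = PKParameters(0.447, cl, v)
        total = 0.0
        for t, y in [(6.0, 1.2), (30.0, 0.7)]:
            f = conc_steady_state(p, 200.0, 56.0, t)
            g = (0.322 * f) ** 2
            total += math.log(2 * math.pi * g) + (y - f) ** 2 / g
        w = np.array([0.387**2, 0.835**2])
        total += sum(math.log(2 * math.pi * wi) for wi in w) + float(np.sum(eta**2 / w))
        assert conditional_m2ll(rec, m, eta) == pytest.approx(total, rel=1e-10)

    def test_observation_at_prediction_with_zero_eta_leaves_normalizers(self):
        m = final_model()
        rec = subject_at_prediction([10.0], [0.0])
        f = conc_steady_state(PKParameters(0.447, 4.54, 227.0), 200.0, 56.0, 10.0)
        g = (0.322 * f) ** 2
        expected = (
            math.log(2 * math.pi * g)
            + math.log(2 * math.pi * 0.387**2)
            + math.log(2 * math.pi * 0.835**2)
        )
        assert conditional_m2ll(rec, m, [0.0, 0.0]) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_deviation_from_prediction(self):
        m = final_model()
        vals = []
        for dev in (0.0, 0.3, 0.8, 1.5):
            rec = subject_at_prediction([10.0], [dev])
            vals.append(conditional_m2ll(rec, m, [0.0, 0.0]))
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestObjective:
    def test_quadrature_agreement_proportional_error(self):
        """The Laplacian FOCE-I objective tracks exact adaptive Gauss-Hermite
        quadrature on sparse (1-2 observation) subjects with typical-sized
        (about one residual SD) deviations."""
        m = final_model()
        cases = [
            subject_at_prediction([10.0], [0.3]),
            subject_at_prediction([40.0], [-0.3]),
            subject_at_prediction([6.0, 30.0], [0.3, -0.3]),
            subject_at_prediction([3.0, 50.0], [-0.2, 0.2]),
        ]
        for rec in cases:
            ofv = foce_objective(m, [rec])
            exact = exact_marginal_m2ll(lambda e: conditional_m2ll(rec, m, e), k=2)
            assert abs(ofv - exact) < 0.5

    def test_quadrature_agreement_additive_error_single_observation(self):
        m = final_model()
        m.sigma_prop = 0.0
        m.sigma_add = 0.1
        m.residual_type = "additive"
        rec = subject_at_prediction([10.0], [0.1])
        ofv = foce_objective(m, [rec])
        exact = exact_marginal_m2ll(lambda e: conditional_m2ll(rec, m, e), k=2)
        assert abs(ofv - exact) < 0.1

    def test_vanishing_iiv_approaches_fixed_effects_likelihood(self):
        rec = make_subject([(6.0, 1.2), (30.0, 0.7)])
        m = final_model()
        # direct fixed-effect -2LL with etas pinned at zero
        p = PKParameters(0.447, 4.54, 227.0)
        direct = 0.0
        for obs in rec.observations:
            f = conc_steady_state(p, 200.0, 56.0, obs.time)
            g = (0.322 * f) ** 2
            direct += math.log(2 * math.pi * g) + (obs.conc - f) ** 2 / g
        prev_gap = None
        for w in (1e-4, 1e-6, 1e-8):
            m.omega2 = {"cl": w, "v": w}
            gap = abs(foce_objective(m, [rec]) - direct)
            if prev_gap is not None:
                assert gap < prev_gap
            prev_gap = gap
        assert prev_gap < 1e-3

    def test_invariant_to_subject_ordering(self, small_dataset):
        records, _, _ = small_dataset
        m = final_model()
        fwd = foce_objective(m, records)
        rev = foce_objective(m, list(reversed(records)))
        assert fwd == pytest.approx(rev, abs=1e-8)

    def test_deterministic_given_model_and_data(self, small_dataset):
        records, _, _ = small_dataset
        m = final_model()
        assert foce_objective(m, records) == foce_objective(m, records)


class TestFit:
    def test_low_noise_theta_recovery(self):
        """With variance components fixed at their (small) generating values,
        the fitted fixed effects land on the generating values."""
        gm = final_model()
        gm.omega2 = {"cl": 0.02**2, "v": 0.02**2}
        gm.sigma_prop = 0.03
        spec = StudyDesignSpec(n_subjects=33, samples_per_subject={4: 33})
        records, _, _ = generate_dataset(spec, gm, seed=5)
        m0 = gm.copy()
        m0.theta = {"ka": 0.35, "cl": 3.5, "v": 180.0}
        m0.effects = [
            CovariateEffect("cl", "GGT", "power", -0.3, 28.9),
            CovariateEffect("cl", "RS319952_GG", "additive", -0.5),
        ]
        res = fit(
            m0, records,
            fix=("omega2.cl", "omega2.v", "sigma.prop"),
            maxfev=900, polish_maxfev=400,
        )
        assert res.converged
        assert res.model.theta["ka"] == pytest.approx(0.447, rel=0.05)
        assert res.model.theta["cl"] == pytest.approx(4.54, rel=0.02)
        assert res.model.theta["v"] == pytest.approx(227.0, rel=0.05)
        assert res.model.effects[0].theta == pytest.approx(-0.476, abs=0.05)

    def test_shrinkage_reported_in_range(self, small_dataset):
        records, _, _ = small_dataset
        res = fit(final_model(), records, maxfev=250, initial_step=0.05, polish_maxfev=0)
        for v in res.eta_shrinkage.values():
            assert 0.0 <= v <= 100.0
        assert -100.0 <= res.eps_shrinkage <= 100.0


class TestEBEShrinkage:
    def test_ebe_dispersion_shrinks_with_sparser_sampling(self):
        """EBEs are pulled toward 0 under sparse data: the dispersion of the
        conditional modes is smaller with 1 sample/subject than with 6."""
        m = final_model()
        sds = {}
        for n_per, label in ((1, "sparse"), (6, "rich")):
            spec = StudyDesignSpec(n_subjects=60, samples_per_subject={n_per: 60})
            records, _, _ = generate_dataset(spec, m, seed=9)
            eng = _Engine(m, records)
            eta, ok, _, _ = eng.eta_modes_deterministic(eng.make_q(m))
            sds[label] = np.std(eta, axis=0, ddof=1)
        assert np.all(sds["sparse"] < sds["rich"])
        assert np.all(sds["sparse"] < np.sqrt([m.omega2["cl"], m.omega2["v"]]))


class TestDiagnostics:
    def test_cwres_calibrated_under_true_model(self, reference_dataset):
        records, _, _ = reference_dataset
        m = final_model()
        diag = diagnostics(m, records)
        assert abs(diag["CWRES"].mean()) < 0.1
        assert 0.85 < diag["CWRES"].std() < 1.15

    def test_ipred_equals_pred_when_ebe_zero(self):
        # additive error: observations at the typical prediction put the
        # conditional mode exactly at eta = 0 (proportional error would not,
        # because the log-variance term shifts the mode)
        m = final_model()
        m.sigma_prop, m.sigma_add, m.residual_type = 0.0, 0.1, "additive"
        rec = subject_at_prediction([8.0, 30.0, 50.0], [0.0, 0.0, 0.0])
        diag = diagnostics(m, [rec])
        np.testing.assert_allclose(diag["IPRED"], diag["PRED"], rtol=1e-6)

    def test_zero_residual_variance_rejected(self):
        with pytest.raises(ValueError):
            PopulationModel(sigma_prop=0.0, sigma_add=0.0, residual_type="combined")
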