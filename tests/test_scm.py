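"""Covariate screening and stepwise selection logic."""

import numpy as np
import pandas as pd
import pytest

import bdqpk.scm as scm_mod
from bdqpk.foce import FitResult
from bdqpk.model import CovariateEffect, base_model
from bdqpk.scm import (
    CovariateCandidate,
    backward_eliminate,
    encode_genotype,
    forward_include,
    impute_missing,
    screen,
)


class TestImputation:
    def test_continuous_missing_filled_with_median(self):
        df = pd.DataFrame({"GGT": [10.0, 30.0, np.nan]})
        out, counts = impute_missing(df, continuous=["GGT"])
        assert out["GGT"].iloc[2] == 20.0
        assert counts == {"GGT": 1}

    def test_categorical_missing_filled_with_mode(self):
        df = pd.DataFrame({"RS319952": ["AA", "AG", "AG", None]})
        out, counts = impute_missing(df, categorical=["RS319952"])
        assert out["RS319952"].iloc[3] == "AG"
        assert counts == {"RS319952": 1}

    def test_no_missing_is_identity(self):
        df = pd.DataFrame({"GGT": [10.0, 30.0], "RS319952": ["AA", "GG"]})
        out, counts = impute_missing(df, continuous=["GGT"], categorical=["RS319952"])
        assert counts == {}
        pd.testing.assert_frame_equal(out, df)

    def test_entirely_missing_raises(self):
        df = pd.DataFrame({"GGT": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing(df, continuous=["GGT"])

    def test_rare_genotype_levels_pooled_before_encoding(self):
        df = pd.DataFrame({"RS319952": ["AA"] * 6 + ["AG"] * 3 + ["GG"]})
        out, col = encode_genotype(df, "RS319952", "GG")
        # the single GG carrier is pooled into the modal level
        assert out[col].sum() == 0.0


def fake_fit(ebes, omega2=(0.15, 0.7)):
    ids = list(range(len(ebes)))
    return FitResult(
        model=base_model(),
        ofv=0.0,
        converged=True,
        n_function_evals=0,
        ebes=np.asarray(ebes),
        eta_names=("cl", "v"),
        subject_ids=ids,
        eta_shrinkage={},
        eps_shrinkage=0.0,
        inner_failures=[],
    )


class TestScreen:
    def test_generating_effect_detected_and_noise_calibrated(self):
        """A GGT effect of the generating size is always retained; an
        independent noise covariate is retained at roughly the nominal 5%."""
        rng = np.random.default_rng(12)
        n = 99
        ggt = np.exp(rng.normal(np.log(30), 0.6, n))
        eta_cl = -0.476 * np.log(ggt / 28.9) + rng.normal(0, 0.387, n)
        fit_res = fake_fit(np.stack([eta_cl, rng.normal(0, 0.8, n)], axis=1))
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            noise = np.exp(rng.normal(3.0, 0.5, n))
            cov = pd.DataFrame({"GGT": ggt, "NOISE": noise}, index=fit_res.subject_ids)
            cands = [
                CovariateCandidate("cl", "GGT", "continuous", reference=28.9),
                CovariateCandidate("cl", "NOISE", "continuous", reference=20.0),
            ]
            kept = screen(fit_res, cov, cands)
            names = {c.covariate for c in kept}
            assert "GGT" in names  # strong generating effect, p ~ 1e-8
            hits += "NOISE" in names
        assert hits / n_rep == pytest.approx(0.05, abs=0.03)

    def test_categorical_screen_detects_group_shift(self):
        rng = np.random.default_rng(3)
        n = 99
        gg = (rng.uniform(size=n) < 0.13).astype(float)
        eta = -0.4 * gg + rng.normal(0, 0.3, n)
        fit_res = fake_fit(np.stack([eta, rng.normal(0, 0.8, n)], axis=1))
        cov = pd.DataFrame({"RS319952_GG": gg}, index=fit_res.subject_ids)
        kept = screen(fit_res, cov, [CovariateCandidate("cl", "RS319952_GG", "categorical")])
        assert len(kept) == 1 and kept[0].p_value < 0.05

    def test_constant_covariate_excluded_with_warning(self):
        fit_res = fake_fit(np.random.default_rng(0).normal(size=(30, 2)))
        cov = pd.DataFrame({"GGT": np.full(30, 30.0)}, index=fit_res.subject_ids)
        kept = screen(fit_res, cov, [CovariateCandidate("cl", "GGT", "continuous", reference=30.0)])
        assert kept == []


class CannedFits:
    """Replaces scm.fit: OFVs looked up by the model's effect-name set."""

    def __init__(self, ofvs, converged=None):
        self.ofvs = {frozenset(k): v for k, v in ofvs.items()}
        self.converged = {frozenset(k): v for k, v in (converged or {}).items()}

    def __call__(self, model, records, **kw):
        key = frozenset(e.name for e in model.effects)
        return FitResult(
            model=model,
            ofv=self.ofvs[key],
            converged=self.converged.get(key, True),
            n_function_evals=1,
            ebes=np.zeros((1, 2)),
            eta_names=("cl", "v"),
            subject_ids=[1],
            eta_shrinkage={},
            eps_shrinkage=0.0,
            inner_failures=[],
        )


GGT = CovariateCandidate("cl", "GGT", "continuous", reference=28.9)
GG = CovariateCandidate("cl", "RS319952_GG", "categorical", form="additive")


class TestForwardBackwardLogic:
    def test_largest_significant_drop_included_first(self, monkeypatch):
        canned = CannedFits({
            (): 100.0,
            (GGT.name,): 80.0,          # dOFV 20
            (GG.name,): 90.0,           # dOFV 10
            (GGT.name, GG.name): 70.0,  # second step dOFV 10
        })
        monkeypatch.setattr(scm_mod, "fit", canned)
        model, ffit, trace = forward_include(base_model(), [GG, GGT], records=[])
        assert {e.name for e in model.effects} == {GGT.name, GG.name}
        accepted = [s.candidate for s in trace.steps if s.accepted]
        assert accepted == [GGT.name, GG.name]

    def test_drop_exactly_at_threshold_not_included(self, monkeypatch):
        # exactly-representable threshold so the boundary comparison is exact
        monkeypatch.setattr(scm_mod, "_lrt_threshold", lambda a, df=1: 8.0)
        canned = CannedFits({(): 100.0, (GGT.name,): 92.0})
        monkeypatch.setattr(scm_mod, "fit", canned)
        model, _, trace = forward_include(base_model(), [GGT], records=[])
        assert model.effects == []

    def test_no_significant_candidate_returns_base(self, monkeypatch):
        canned = CannedFits({(): 100.0, (GGT.name,): 95.0})
        monkeypatch.setattr(scm_mod, "fit", canned)
        model, _, _ = forward_include(base_model(), [GGT], records=[])
        assert model.effects == []

    def test_nonconverged_candidate_skipped(self, monkeypatch):
        canned = CannedFits(
            {(): 100.0, (GGT.name,): 50.0, (GG.name,): 85.0, (GGT.name, GG.name): 84.0},
            converged={(GGT.name,): False, (GGT.name, GG.name): False},
        )
        monkeypatch.setattr(scm_mod, "fit", canned)
        model, _, trace = forward_include(base_model(), [GGT, GG], records=[])
        assert {e.name for e in model.effects} == {GG.name}

    def test_backward_removes_weak_keeps_strong(self, monkeypatch):
        full = base_model().with_effect(GGT.effect(-0.4)).with_effect(GG.effect(-1.0))
        canned = CannedFits({
            (GGT.name, GG.name): 70.0,
            (GG.name,): 90.0,   # removing GGT costs 20: retained
            (GGT.name,): 74.0,  # removing GG costs 4: removed
            (): 95.0,           # then removing GGT costs 21: retained
        })
        monkeypatch.setattr(scm_mod, "fit", canned)
        model, _, trace = backward_eliminate(full, records=[])
        assert [e.name for e in model.effects] == [GGT.name]

    def test_rise_exactly_at_threshold_removed(self, monkeypatch):
        monkeypatch.setattr(scm_mod, "_lrt_threshold", lambda a, df=1: 8.0)
        full = base_model().with_effect(GGT.effect(-0.4))
        canned = CannedFits({(GGT.name,): 70.0, (): 78.0})
        monkeypatch.setattr(scm_mod, "fit", canned)
        model, _, _ = backward_eliminate(full, records=[])
        assert model.effects == []

    def test_empty_effect_set_is_identity(self, monkeypatch):
        canned = CannedFits({(): 100.0})
        monkeypatch.setattr(scm_mod, "fit", canned)
        model, _, trace = backward_eliminate(base_model(), records=[])
        assert model.effects == [] and trace.steps == []

    def test_trace_ofv_sequence_nonincreasing_over_forward_steps(self, monkeypatch):
        canned = CannedFits({
            (): 100.0,
            (GGT.name,): 80.0,
            (GG.name,): 88.0,
            (GGT.name, GG.name): 72.0,
        })
        monkeypatch.setattr(scm_mod, "fit", canned)
        _, final_fit, trace = forward_include(base_model(), [GGT, GG], records=[])
        assert final_fit.ofv == 72.0  # monotone path 100 -> 80 -> 72
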