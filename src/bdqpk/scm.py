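"""Covariate screening and stepwise covariate modeling (SCM).

Candidate covariate-parameter relations are first screened on the base
model's empirical Bayes estimates (EBEs): for continuous covariates a
regression of the subject's eta on the log covariate, for categorical
covariates a one-way ANOVA of etas across groups, retaining relations with
p < 0.05.  Retained candidates then enter a forward-inclusion /
backward-elimination search using the likelihood-ratio test on the FOCE
objective: forward at alpha = 0.01 (dOFV > 6.635 for 1 df, strict),
backward at alpha = 0.005 (an effect is retained only if removing it would
raise the OFV by more than 7.879).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import SubjectRecord
from .foce import FitResult, fit
from .model import CovariateEffect, PopulationModel

__all__ = [
    "CovariateCandidate",
    "ScmStep",
    "ScmTrace",
    "FORWARD_ALPHA",
    "BACKWARD_ALPHA",
    "impute_missing",
    "encode_genotype",
    "screen",
    "forward_include",
    "backward_eliminate",
    "stepwise",
]

logger = logging.getLogger(__name__)

FORWARD_ALPHA = 0.01
BACKWARD_ALPHA = 0.005


@dataclass(frozen=True)
class CovariateCandidate:
    """One candidate parameter-covariate relation for the SCM search.

    Continuous candidates use the power form (normalized at `reference`,
    usually the covariate median); categorical candidates use a shift form
    on a 0/1 indicator column ("fractional" by default, "additive" for an
    absolute shift in the parameter's units).
    """

    parameter: str
    covariate: str
    kind: str  # "continuous" | "categorical"
    form: str = ""
    reference: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown candidate kind {self.kind!r}")
        form = self.form or ("power" if self.kind == "continuous" else "fractional")
        object.__setattr__(self, "form", form)
        if self.kind == "continuous" and self.form != "power":
            raise ValueError("continuous candidates use the power form")
        if self.kind == "categorical" and self.form not in ("fractional", "additive"):
            raise ValueError("categorical candidates use a shift form")

    def effect(self, theta: float = 0.0) -> CovariateEffect:
        return CovariateEffect(
            self.parameter, self.covariate, self.form, theta=theta, reference=self.reference
        )

    @property
    def name(self) -> str:
        return f"{self.covariate}~{self.parameter}:{self.form}"


@dataclass(frozen=True)
class ScmStep:
    phase: str  # "forward" | "backward"
    candidate: str
    delta_ofv: float
    df: int
    threshold: float
    accepted: bool  # forward: included; backward: removed
    note: str = ""


@dataclass
class ScmTrace:
    steps: list[ScmStep] = field(default_factory=list)

    def append(self, step: ScmStep) -> None:
        self.steps.append(step)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])


# ---------------------------------------------------------------------------
# Imputation and encoding
# ---------------------------------------------------------------------------


def impute_missing(
    covariates: pd.DataFrame,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Fill missing covariate values; returns (filled frame, imputation counts).

    Continuous covariates are filled with the median of the observed values,
    categorical covariates with the modal (most frequent) category.  Raises
    if a named covariate has no observed values at all.
    """
    out = covariates.copy()
    counts: dict[str, int] = {}
    for col in continuous:
        vals = pd.to_numeric(out[col], errors="coerce")
        if vals.notna().sum() == 0:
            raise ValueError(f"covariate {col!r} is entirely missing")
        n_miss = int(vals.isna().sum())
        if n_miss:
            out[col] = vals.fillna(float(vals.median()))
            counts[col] = n_miss
            logger.info("imputed %d missing %s values with median %.4g", n_miss, col, vals.median())
    for col in categorical:
        vals = out[col]
        missing = vals.isna() | (vals.astype("object") == "") | vals.isin([None])
        if missing.all():
            raise ValueError(f"covariate {col!r} is entirely missing")
        n_miss = int(missing.sum())
        if n_miss:
            mode = vals[~missing].mode().iloc[0]
            out.loc[missing, col] = mode
            counts[col] = n_miss
            logger.info("imputed %d missing %s calls with mode %r", n_miss, col, mode)
    return out, counts


def encode_genotype(
    covariates: pd.DataFrame,
    snp: str,
    level: str,
    *,
    min_group: int = 2,
) -> tuple[pd.DataFrame, str]:
    """Add a 0/1 indicator column ``<snp>_<level>`` for carrying `level`.

    Genotype levels seen in fewer than `min_group` subjects are pooled into
    the modal level first (logged), so degenerate contrasts cannot arise.
    Missing calls must have been imputed beforehand.
    """
    out = covariates.copy()
    vals = out[snp].astype("object")
    if vals.isna().any():
        raise ValueError(f"{snp!r} still has missing calls; impute first")
    freq = vals.value_counts()
    rare = freq[freq < min_group].index
    if len(rare):
        mode = freq.idxmax()
        logger.info("pooling rare %s levels %s into %r", snp, list(rare), mode)
        vals = vals.where(~vals.isin(rare), mode)
    col = f"{snp}_{level}"
    out[col] = (vals == level).astype(float)
    return out, col


def apply_covariates_to_records(
    records: Sequence[SubjectRecord], covariates: pd.DataFrame
) -> list[SubjectRecord]:
    """Return records with covariate dicts replaced by rows of `covariates` (indexed by ID)."""
    out = []
    for r in records:
        row = covariates.loc[r.id]
        out.append(replace(r, covariates=row.to_dict()))
    return out


# ---------------------------------------------------------------------------
# Screening on EBEs
# ---------------------------------------------------------------------------


def screen(
    base_fit: FitResult,
    covariates: pd.DataFrame,
    candidates: Sequence[CovariateCandidate],
    alpha: float = 0.05,
) -> list[CovariateCandidate]:
    """Screen candidates against the base model's EBEs; keep those with p < alpha.

    Continuous: t-test of the slope in a regression of the subject's eta on
    the log covariate.  Categorical: one-way ANOVA of etas across the
    covariate's groups.  Covariates without variation are excluded with a
    warning.  `covariates` must be indexed by subject ID and imputed/encoded.
    """
    ebes = pd.DataFrame(
        base_fit.ebes, columns=[f"eta_{p}" for p in base_fit.eta_names], index=base_fit.subject_ids
    )
    cov = covariates.loc[ebes.index]
    kept: list[CovariateCandidate] = []
    for cand in candidates:
        if cand.parameter not in base_fit.eta_names:
            raise ValueError(
                f"candidate {cand.name}: no eta on {cand.parameter!r} in the base model"
            )
        y = ebes[f"eta_{cand.parameter}"].to_numpy()
        x = cov[cand.covariate]
        if cand.kind == "continuous":
            xv = pd.to_numeric(x, errors="coerce").to_numpy(dtype=float)
            if np.all(xv <= 0) or np.ptp(xv) == 0:
                logger.warning("candidate %s: covariate has no usable variation; excluded", cand.name)
                continue
            res = stats.linregress(np.log(xv), y)
            p = float(res.pvalue)
        else:
            groups = [y[(x == lvl).to_numpy()] for lvl in pd.unique(x)]
            groups = [g for g in groups if len(g) >= 2]
            if len(groups) < 2:
                logger.warning("candidate %s: fewer than two usable groups; excluded", cand.name)
                continue
            p = float(stats.f_oneway(*groups).pvalue)
        if p < alpha:
            kept.append(replace(cand, p_value=p))
        else:
            logger.info("candidate %s screened out (p = %.3g)", cand.name, p)
    return kept


# ---------------------------------------------------------------------------
# Stepwise search
# ---------------------------------------------------------------------------


def _lrt_threshold(alpha: float, df: int = 1) -> float:
    return float(stats.chi2.ppf(1.0 - alpha, df))


def forward_include(
    base: PopulationModel,
    candidates: Sequence[CovariateCandidate],
    records: Sequence[SubjectRecord],
    *,
    alpha: float = FORWARD_ALPHA,
    base_fit_result: FitResult | None = None,
    **fit_kwargs,
) -> tuple[PopulationModel, FitResult, ScmTrace]:
    """Forward inclusion: repeatedly add the candidate with the largest
    significant drop in OFV (strictly greater than the chi-square quantile,
    1 df) until none qualifies.  Candidate fits that fail to converge are
    skipped and logged in the trace."""
    trace = ScmTrace()
    threshold = _lrt_threshold(alpha)
    current_fit = base_fit_result if base_fit_result is not None else fit(base, records, **fit_kwargs)
    current = current_fit.model
    remaining = list(candidates)
    while remaining:
        results: list[tuple[CovariateCandidate, FitResult]] = []
        for cand in remaining:
            trial = current.with_effect(cand.effect(0.0))
            r = fit(trial, records, **fit_kwargs)
            if not r.converged:
                trace.append(ScmStep("forward", cand.name, np.nan, 1, threshold, False, "non-converged; skipped"))
                logger.warning("forward: candidate %s did not converge; skipped", cand.name)
                continue
            results.append((cand, r))
        sig = [(c, r) for c, r in results if current_fit.ofv - r.ofv > threshold]
        for c, r in results:
            if (c, r) not in sig:
                trace.append(ScmStep("forward", c.name, current_fit.ofv - r.ofv, 1, threshold, False))
        if not sig:
            break
        # largest dOFV wins; ties broken by candidate order (deterministic)
        best_c, best_r = max(sig, key=lambda cr: (current_fit.ofv - cr[1].ofv, -remaining.index(cr[0])))
        trace.append(ScmStep("forward", best_c.name, current_fit.ofv - best_r.ofv, 1, threshold, True))
        logger.info("forward: included %s (dOFV = %.2f)", best_c.name, current_fit.ofv - best_r.ofv)
        current, current_fit = best_r.model, best_r
        remaining = [c for c in remaining if c is not best_c]
    return current, current_fit, trace


def backward_eliminate(
    full: PopulationModel,
    records: Sequence[SubjectRecord],
    *,
    alpha: float = BACKWARD_ALPHA,
    full_fit_result: FitResult | None = None,
    removable: Sequence[str] | None = None,
    **fit_kwargs,
) -> tuple[PopulationModel, FitResult, ScmTrace]:
    """Backward elimination: repeatedly remove the effect whose removal
    raises the OFV least, as long as that rise does not exceed the
    chi-square quantile (retention requires a strictly larger rise)."""
    trace = ScmTrace()
    threshold = _lrt_threshold(alpha)
    current_fit = full_fit_result if full_fit_result is not None else fit(full, records, **fit_kwargs)
    current = current_fit.model
    while True:
        names = [e.name for e in current.effects if removable is None or e.name in removable]
        if not names:
            break
        rises: list[tuple[str, FitResult, float]] = []
        for name in names:
            reduced = current.without_effect(name)
            r = fit(reduced, records, **fit_kwargs)
            if not r.converged:
                trace.append(ScmStep("backward", name, np.nan, 1, threshold, False, "reduced fit non-converged; effect kept"))
                logger.warning("backward: reduced fit without %s did not converge", name)
                continue
            rises.append((name, r, r.ofv - current_fit.ofv))
        if not rises:
            break
        name, r, rise = min(rises, key=lambda t: t[2])
        if rise > threshold:  # every remaining effect is significant
            for nm, _, rs in rises:
                trace.append(ScmStep("backward", nm, rs, 1, threshold, False))
            break
        trace.append(ScmStep("backward", name, rise, 1, threshold, True))
        logger.info("backward: removed %s (dOFV = %.2f)", name, rise)
        current, current_fit = r.model, r
    return current, current_fit, trace


def stepwise(
    base: PopulationModel,
    candidates: Sequence[CovariateCandidate],
    records: Sequence[SubjectRecord],
    *,
    forward_alpha: float = FORWARD_ALPHA,
    backward_alpha: float = BACKWARD_ALPHA,
    base_fit_result: FitResult | None = None,
    **fit_kwargs,
) -> tuple[PopulationModel, FitResult, ScmTrace]:
    """Full SCM: forward inclusion then backward elimination of the included set."""
    model, fwd_fit, trace = forward_include(
        base, candidates, records,
        alpha=forward_alpha, base_fit_result=base_fit_result, **fit_kwargs,
    )
    added = [s.candidate for s in trace.steps if s.phase == "forward" and s.accepted]
    if added:
        model, fwd_fit, btrace = backward_eliminate(
            model, records,
            alpha=backward_alpha, full_fit_result=fwd_fit, removable=added, **fit_kwargs,
        )
        trace.steps.extend(btrace.steps)
    return model, fwd_fit, trace
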