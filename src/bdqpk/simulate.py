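"""Synthetic datasets emulating the bedaquiline MDR-TB study design.

The generator reproduces the study's statistical structure: 99 subjects
contributing 246 sparse concentration samples (per-subject sample counts
38x1, 24x2, 12x3, 11x4, 7x5, 5x6, 1x7, 1x8), drawn at random times within a
56-h steady-state dosing interval of 200 mg thrice weekly; continuous
baseline covariates from truncated normal distributions matching the
reported means/SDs/ranges; SNP genotypes from the reported genotype counts
(including the reported missing fractions); proportional residual error;
and substitution of sub-LOD values by the assay LOD of 0.024 mg/L.

Covariates are drawn independently of one another (no joint structure was
reported); the study's 400 mg daily two-week lead-in does not affect the
steady state sampled here and is not generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq, fsolve
from scipy.stats import truncnorm

from .data import Observation, SubjectRecord, from_subject_records
from .model import PopulationModel, final_model
from .pk import DoseEvent

__all__ = [
    "CONTINUOUS_COVARIATES",
    "SNP_GENOTYPE_COUNTS",
    "SAMPLES_PER_SUBJECT",
    "StudyDesignSpec",
    "generate_covariates",
    "generate_dataset",
    "default_generating_model",
]

#: continuous baseline covariates: (mean, SD, min, max)
CONTINUOUS_COVARIATES: dict[str, tuple[float, float, float, float]] = {
    "AGE": (38.1, 14.1, 11.0, 78.0),
    "HT": (166.4, 12.4, 73.3, 183.0),  # printed lower bound kept as-is
    "WT": (58.0, 12.6, 17.0, 90.7),
    "ALT": (28.6, 24.2, 6.0, 138.8),
    "AST": (38.5, 24.0, 14.5, 176.1),
    "GGT": (36.4, 31.1, 8.0, 271.8),
    "TP": (77.5, 5.8, 65.4, 94.6),
    "ALB": (46.2, 3.3, 38.2, 55.6),
}

#: genotype counts out of 99 subjects per SNP; "NA" rows are missing calls
SNP_GENOTYPE_COUNTS: dict[str, dict[str | None, int]] = {
    "RS1045642": {"AA": 11, "GG": 27, "AG": 45, None: 16},
    "RS3740065": {"AA": 33, "AG": 40, "GG": 10, None: 16},
    "RS319952": {"AA": 31, "AG": 39, "GG": 13, None: 16},
    "RS320003": {"AA": 12, "GG": 69, None: 18},
    "RS2070401": {"AA": 50, "GG": 4, "AG": 29, None: 16},
    "RS9332096": {"CC": 77, "CT": 6, None: 16},
    "RS4986893": {"AG": 7, "GG": 76, None: 16},
    "RS2031920": {"CC": 46, "TT": 3, "CT": 12, None: 38},
    "RS1695": {"AA": 53, "GG": 1, "AG": 28, None: 17},
    "RS11080344": {"CC": 29, "TT": 18, "CT": 36, None: 16},
    "RS10946739": {"CC": 55, "CT": 28, None: 16},
    "RS4149056": {"CC": 8, "TT": 59, "CT": 15, None: 17},
    "RS1495741": {"AA": 18, "AG": 38, "GG": 26, None: 17},
    "RS11125883": {"AA": 30, "CC": 13, "AC": 40, None: 16},
}

#: samples-per-subject distribution: {n_samples: n_subjects}
SAMPLES_PER_SUBJECT: dict[int, int] = {1: 38, 2: 24, 3: 12, 4: 11, 5: 7, 6: 5, 7: 1, 8: 1}


@dataclass
class StudyDesignSpec:
    """Design of the sparse steady-state sampling study."""

    n_subjects: int = 99
    samples_per_subject: Mapping[int, int] = field(
        default_factory=lambda: dict(SAMPLES_PER_SUBJECT)
    )
    dose: float = 200.0
    tau: float = 56.0
    lod: float = 0.024
    continuous: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(CONTINUOUS_COVARIATES)
    )
    snps: Mapping[str, Mapping[str | None, int]] = field(
        default_factory=lambda: dict(SNP_GENOTYPE_COUNTS)
    )

    def __post_init__(self) -> None:
        for name, (mu, sd, lo, hi) in self.continuous.items():
            if not (lo < hi and sd >= 0):
                raise ValueError(f"infeasible truncation for covariate {name!r}")
        for snp, counts in self.snps.items():
            if sum(counts.values()) <= 0:
                raise ValueError(f"SNP {snp!r} has no genotype counts")

    def subject_sample_counts(self) -> np.ndarray:
        """Per-subject observation counts; for n_subjects != 99 the printed
        distribution pattern is tiled deterministically and truncated."""
        pattern = np.repeat(
            list(self.samples_per_subject.keys()),
            list(self.samples_per_subject.values()),
        )
        reps = math.ceil(self.n_subjects / len(pattern))
        return np.tile(pattern, reps)[: self.n_subjects]

    @property
    def n_observations(self) -> int:
        return int(self.subject_sample_counts().sum())


@lru_cache(maxsize=None)
def _truncnorm_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Underlying (loc, scale) whose [lo, hi]-truncated normal has the given
    mean and SD, so generated samples reproduce the reported summaries even
    for covariates whose range clips one tail (e.g. GGT)."""

    def moments(x):
        loc, log_scale = x
        scale = math.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol, info, ier, _ = fsolve(moments, [mean, math.log(sd)], full_output=True)
    if ier == 1 and max(abs(r) for r in moments(sol)) < 1e-6 * max(sd, 1.0):
        return float(sol[0]), float(math.exp(sol[1]))
    # the printed SD can exceed what any truncated normal with this mean
    # supports (heavily skewed labs); match the mean exactly instead
    def mean_resid(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(truncnorm.stats(a, b, loc=loc, scale=sd, moments="m")) - mean

    lo_loc, hi_loc = mean - 20 * sd, mean + 20 * sd
    sol2 = brentq(mean_resid, lo_loc, hi_loc)
    return float(sol2), sd


def default_generating_model() -> PopulationModel:
    """The reference generating model (the final-model population estimates)."""
    return final_model()


def generate_covariates(spec: StudyDesignSpec, seed: int | np.random.Generator) -> pd.DataFrame:
    """Draw one row of baseline covariates per subject.

    Continuous labs come from normal distributions truncated to the reported
    ranges; genotypes are drawn per reported genotype counts, with the "NA"
    fraction emitted as missing values (left un-imputed here so downstream
    imputation is exercised).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = spec.n_subjects
    out: dict[str, object] = {"ID": np.arange(1, n + 1)}
    for name, (mu, sd, lo, hi) in spec.continuous.items():
        if sd == 0:
            out[name] = np.full(n, mu)
            continue
        loc, scale = _truncnorm_params(mu, sd, lo, hi)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        out[name] = truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
    for snp, counts in spec.snps.items():
        levels = list(counts.keys())
        probs = np.asarray([counts[l] for l in levels], dtype=float)
        probs /= probs.sum()
        draw = rng.choice(len(levels), size=n, p=probs)
        out[snp] = pd.array([levels[i] for i in draw], dtype="object")
    return pd.DataFrame(out)


def generate_dataset(
    spec: StudyDesignSpec,
    gm: PopulationModel | None = None,
    seed: int | np.random.Generator = 0,
    *,
    zero_eta: bool = False,
    zero_sigma: bool = False,
):
    """Simulate a full study dataset from the generating model.

    Per subject: draw etas from the IIV distribution, compute individual
    parameters from the covariates, sample observation times uniformly in
    (0, tau], evaluate the steady-state concentration, apply residual error
    (negative draws resampled, preserving the error model's support), and
    substitute values below the LOD by the LOD value (flagged BLQ).

    Returns (records, table, truth): subject records, the NONMEM-style table,
    and a truth dict (generating parameters, per-subject etas and sample
    times) for recovery tests.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    gm = default_generating_model() if gm is None else gm
    cov = generate_covariates(spec, rng)
    counts = spec.subject_sample_counts()
    n = spec.n_subjects
    k = gm.n_eta
    w_sd = np.sqrt([gm.omega2[p] for p in gm.eta_names])
    etas = np.zeros((n, k)) if zero_eta else rng.normal(size=(n, k)) * w_sd

    # covariates used by the generating model must be complete & encoded:
    # the GG indicator from the (possibly missing) genotype call, missing -> 0
    cov = cov.copy()
    if "RS319952" in cov:
        gg = cov["RS319952"].astype("object") == "GG"
        cov["RS319952_GG"] = gg.astype(float)

    records: list[SubjectRecord] = []
    n_blq = 0
    n_resampled = 0
    for i in range(n):
        row = cov.iloc[i]
        covariates = row.drop(labels=["ID"]).to_dict()
        typ = gm.typical_values(covariates)
        ind = dict(typ)
        for name, e in zip(gm.eta_names, etas[i]):
            ind[name] *= math.exp(e)
        ka, cl, v, ke = ind["ka"], ind["cl"], ind["v"], ind["cl"] / ind["v"]
        times = rng.uniform(0.0, spec.tau, size=int(counts[i]))
        pref = spec.dose * ka / (v * (ka - ke))
        f = pref * (
            np.exp(-ke * times) / (1 - math.exp(-ke * spec.tau))
            - np.exp(-ka * times) / (1 - math.exp(-ka * spec.tau))
        )
        if zero_sigma:
            y = f.copy()
        else:
            y = np.empty_like(f)
            for j, fj in enumerate(f):
                while True:
                    if gm.residual_type == "proportional":
                        val = fj * (1.0 + rng.normal() * gm.sigma_prop)
                    elif gm.residual_type == "additive":
                        val = fj + rng.normal() * gm.sigma_add
                    else:
                        val = fj * (1.0 + rng.normal() * gm.sigma_prop) + rng.normal() * gm.sigma_add
                    if val > 0:
                        y[j] = val
                        break
                    n_resampled += 1
        blq = y < spec.lod
        n_blq += int(blq.sum())
        y = np.where(blq, spec.lod, y)
        obs = tuple(
            Observation(time=float(t), conc=float(c), below_lod=bool(b))
            for t, c, b in zip(times, y, blq)
        )
        records.append(
            SubjectRecord(
                id=int(row["ID"]),
                doses=(DoseEvent(spec.dose, 0.0, ss=True, tau=spec.tau),),
                observations=obs,
                covariates=covariates,
            )
        )
    table = from_subject_records(records)
    truth = {
        "theta": dict(gm.theta),
        "effects": {e.name: e.theta for e in gm.effects},
        "omega2": dict(gm.omega2),
        "sigma_prop": gm.sigma_prop,
        "sigma_add": gm.sigma_add,
        "residual_type": gm.residual_type,
        "etas": etas.tolist(),
        "eta_names": list(gm.eta_names),
        "n_below_lod": n_blq,
        "n_resampled_negative": n_resampled,
    }
    return records, table, truth
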