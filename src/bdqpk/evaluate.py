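"""Model evaluation: nonparametric bootstrap and prediction-corrected VPC.

The bootstrap resamples subjects (not observations) with replacement to the
original subject count and refits each resample; only converged refits
enter the summaries, and the convergence success rate is reported.

The prediction-corrected visual predictive check (pcVPC) rescales every
observed and simulated concentration by (bin median population prediction /
its own population prediction), then compares observed percentiles per
time-after-dose bin with 90% confidence bands obtained from model
simulations of the original design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data import Observation, SubjectRecord
from .foce import FitResult, _Engine, fit
from .model import PopulationModel

__all__ = ["BootstrapResult", "VPCSummary", "bootstrap", "pc_vpc", "simulate_observations"]

logger = logging.getLogger(__name__)


@dataclass
class BootstrapResult:
    """Converged resample estimates with medians and 5th-95th percentiles."""

    estimates: pd.DataFrame  # one row per converged resample
    medians: pd.Series
    p5: pd.Series
    p95: pd.Series
    success_rate: float  # % of resamples whose refit converged
    n_resamples: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"median": self.medians, "p5": self.p5, "p95": self.p95})


def bootstrap(
    records: Sequence[SubjectRecord],
    m: PopulationModel,
    n_resamples: int = 1000,
    seed: int = 0,
    **fit_kwargs,
) -> BootstrapResult:
    """Nonparametric subject-level bootstrap of the model fit.

    Each resample draws len(records) subjects with replacement (re-labelled
    with unique IDs) and refits starting from `m` (normally the original
    fit's estimates, which speeds convergence).  Raises if no resample
    converges.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(records)
    rows = []
    n_ok = 0
    for b in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        sample = [replace(records[i], id=f"b{b}_{j}") for j, i in enumerate(idx)]
        try:
            r = fit(m, sample, **fit_kwargs)
        except Exception as exc:  # numerical failure counts as non-convergence
            logger.warning("bootstrap resample %d failed: %s", b, exc)
            continue
        if not r.converged:
            continue
        n_ok += 1
        rows.append(r.estimates())
    if not rows:
        raise RuntimeError("no bootstrap resample converged")
    est = pd.DataFrame(rows).drop(columns=["ofv"])
    return BootstrapResult(
        estimates=est,
        medians=est.median(),
        p5=est.quantile(0.05),
        p95=est.quantile(0.95),
        success_rate=100.0 * n_ok / n_resamples,
        n_resamples=n_resamples,
    )


# ---------------------------------------------------------------------------
# pcVPC
# ---------------------------------------------------------------------------


@dataclass
class VPCSummary:
    """Binned pcVPC summary.

    `table` has one row per (bin, percentile in {5, 50, 95}) with the
    observed prediction-corrected percentile and the 90% simulation band
    (sim_lo, sim_med, sim_hi); bin edges partition time after dose.
    """

    table: pd.DataFrame
    bin_edges: np.ndarray
    n_sim: int

    def coverage(self) -> float:
        """Fraction of (bin, percentile) points whose observed value lies
        inside its 90% simulation band."""
        t = self.table
        inside = (t["observed"] >= t["sim_lo"]) & (t["observed"] <= t["sim_hi"])
        return float(inside.mean())


def simulate_observations(
    records: Sequence[SubjectRecord],
    m: PopulationModel,
    rng: np.random.Generator,
    lod: float | None = None,
) -> np.ndarray:
    """Simulate one replicate of all observations under the model.

    Uses the original design (subjects, times, dosing, covariates); draws
    fresh etas and residuals; negative concentrations are redrawn; values
    below `lod` are substituted by it, mirroring the assay handling.
    """
    eng = _Engine(m, records)
    typ = eng.typical_arrays(m)
    k = m.n_eta
    w_sd = np.sqrt([m.omega2[p] for p in m.eta_names])
    eta = rng.normal(size=(eng.n_subj, k)) * w_sd
    col = {p: j for j, p in enumerate(m.eta_names)}
    cl = typ["cl"] * np.exp(eta[:, col["cl"]]) if "cl" in col else typ["cl"]
    v = typ["v"] * np.exp(eta[:, col["v"]]) if "v" in col else typ["v"]
    f = np.real(eng.predict(typ["ka"][0], cl, v))
    y = np.empty_like(f)
    todo = np.ones(len(f), dtype=bool)
    for _ in range(100):
        ndraw = int(todo.sum())
        if not ndraw:
            break
        if m.residual_type == "proportional":
            draw = f[todo] * (1.0 + rng.normal(size=ndraw) * m.sigma_prop)
        elif m.residual_type == "additive":
            draw = f[todo] + rng.normal(size=ndraw) * m.sigma_add
        else:
            draw = f[todo] * (1.0 + rng.normal(size=ndraw) * m.sigma_prop) + rng.normal(size=ndraw) * m.sigma_add
        y[todo] = draw
        todo = todo & (y <= 0)
    if lod is not None:
        y = np.maximum(y, lod)
    return y


def pc_vpc(
    records: Sequence[SubjectRecord],
    m: PopulationModel,
    n_sim: int = 1000,
    bins: int = 8,
    seed: int = 0,
    lod: float | None = None,
    percentiles: tuple[float, float, float] = (5.0, 50.0, 95.0),
) -> VPCSummary:
    """Prediction-corrected VPC of the model against the observed data.

    Bins are equal-count over time after dose; bins ending up with fewer
    than 2 observations are merged with their neighbour (logged).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    eng = _Engine(m, records)
    typ = eng.typical_arrays(m)
    pred = np.real(eng.predict(typ["ka"][0], typ["cl"], typ["v"]))
    times = eng.t_obs
    y_obs = eng.y

    # equal-count bin edges on time after dose
    qs = np.linspace(0, 1, bins + 1)
    edges = np.unique(np.quantile(times, qs))
    idx = np.clip(np.digitize(times, edges[1:-1]), 0, len(edges) - 2)
    # merge undersized bins with their left neighbour
    while len(edges) > 2:
        counts = np.bincount(idx, minlength=len(edges) - 1)
        small = np.flatnonzero(counts < 2)
        if not len(small):
            break
        b = small[0]
        logger.info("merging undersized VPC bin %d (n=%d) with neighbour", b, counts[b])
        edges = np.delete(edges, b if b > 0 else 1)
        idx = np.clip(np.digitize(times, edges[1:-1]), 0, len(edges) - 2)
    n_bins = len(edges) - 1

    # prediction correction factors: bin-median PRED / own PRED
    bin_med_pred = np.array([np.median(pred[idx == b]) for b in range(n_bins)])
    corr = bin_med_pred[idx] / pred

    obs_pc = y_obs * corr
    obs_stat = np.empty((n_bins, 3))
    for b in range(n_bins):
        obs_stat[b] = np.percentile(obs_pc[idx == b], percentiles)

    sim_stat = np.empty((n_sim, n_bins, 3))
    for s in range(n_sim):
        y_sim = simulate_observations(records, m, rng, lod=lod) * corr
        for b in range(n_bins):
            sim_stat[s, b] = np.percentile(y_sim[idx == b], percentiles)
    lo = np.percentile(sim_stat, 5.0, axis=0)
    med = np.percentile(sim_stat, 50.0, axis=0)
    hi = np.percentile(sim_stat, 95.0, axis=0)

    rows = []
    for b in range(n_bins):
        for j, pct in enumerate(percentiles):
            rows.append(
                {
                    "bin": b,
                    "t_lo": edges[b],
                    "t_hi": edges[b + 1],
                    "n_obs": int((idx == b).sum()),
                    "percentile": pct,
                    "observed": obs_stat[b, j],
                    "sim_lo": lo[b, j],
                    "sim_med": med[b, j],
                    "sim_hi": hi[b, j],
                }
            )
    return VPCSummary(table=pd.DataFrame(rows), bin_edges=edges, n_sim=n_sim)
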