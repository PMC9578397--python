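"""One-compartment oral-absorption kinetics and steady-state exposure metrics.

Structural model: first-order absorption from a depot into a central
compartment with first-order elimination, parameterized in the apparent
(bioavailability-scaled) clearance CL/F and central volume Vc/F.  Units are
hours, milligrams, litres and mg/L throughout (mg/L is numerically equal to
the assay's ug/mL).

The thrice-weekly maintenance regimen is represented at steady state as
evenly spaced 200 mg doses every tau = 56 h (168 h / 3 doses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RATE_TOL",
    "PKParameters",
    "CovariateModel",
    "DoseEvent",
    "Regimen",
    "ExposureMetrics",
    "apply_covariates",
    "conc_single_dose",
    "conc_steady_state",
    "conc_profile",
    "tmax_steady_state",
    "exposure_metrics",
]

#: relative |ka - ke| below which the Bateman denominator is treated as degenerate
RATE_TOL = 1e-8


@dataclass(frozen=True)
class PKParameters:
    """Apparent individual PK parameters.

    ka : first-order absorption rate constant (1/h)
    cl : apparent clearance CL/F (L/h)
    v  : apparent central volume Vc/F (L)
    """

    ka: float
    cl: float
    v: float

    def __post_init__(self) -> None:
        for name in ("ka", "cl", "v"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val > 0):
                raise ValueError(f"PKParameters.{name} must be finite and > 0, got {val!r}")

    @property
    def ke(self) -> float:
        """Elimination rate constant CL/V (1/h)."""
        return self.cl / self.v

    def is_degenerate(self) -> bool:
        """True when ka and ke coincide to within RATE_TOL (flip-flop limit)."""
        return abs(self.ka - self.ke) <= RATE_TOL * max(self.ka, self.ke)


@dataclass(frozen=True)
class CovariateModel:
    """Covariate model for typical apparent clearance.

    CL/F = base_cl * (GGT / ggt_reference)^ggt_exponent  (+ genotype_shift if GG)

    The continuous gamma-glutamyl-transferase (GGT) effect is a power model
    normalized at the study median; the rs319952 genotype effect is an
    additive shift (L/h) for homozygous GG carriers relative to AA/AG.
    """

    base_cl: float = 4.54
    ggt_exponent: float = -0.476
    ggt_reference: float = 28.9
    genotype_shift: float = -1.4

    def __post_init__(self) -> None:
        if self.ggt_reference <= 0:
            raise ValueError("ggt_reference must be > 0")


def apply_covariates(cm: CovariateModel, ggt: float, rs319952_gg: bool) -> float:
    """Typical CL/F (L/h) at a GGT level (U/L) and rs319952 genotype.

    Raises ValueError if the covariate combination would drive CL/F <= 0
    (possible at very high GGT together with the GG shift).
    """
    if not ggt > 0:
        raise ValueError(f"GGT must be > 0, got {ggt!r}")
    cl = cm.base_cl * (ggt / cm.ggt_reference) ** cm.ggt_exponent
    if rs319952_gg:
        cl = cl + cm.genotype_shift
    if not cl > 0:
        raise ValueError(
            f"covariate model yields non-positive CL/F ({cl:.4g} L/h) "
            f"at GGT={ggt}, GG={rs319952_gg}"
        )
    return cl


@dataclass(frozen=True)
class DoseEvent:
    """A single dose: amount (mg) given at `time` (h).

    With ``ss=True`` the event initializes the system at the periodic steady
    state of `amount` given every `tau` hours, mirroring the NONMEM SS/II
    data items.
    """

    amount: float
    time: float = 0.0
    ss: bool = False
    tau: float | None = None

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise ValueError("dose amount must be > 0")
        if self.ss and not (self.tau is not None and self.tau > 0):
            raise ValueError("steady-state dose events require tau > 0")


@dataclass(frozen=True)
class Regimen:
    """Ordered sequence of dose events."""

    doses: tuple[DoseEvent, ...]

    def __post_init__(self) -> None:
        times = [d.time for d in self.doses]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose times must be nondecreasing")

    @classmethod
    def single(cls, amount: float, time: float = 0.0) -> "Regimen":
        return cls((DoseEvent(amount, time),))

    @classmethod
    def repeated(cls, amount: float, tau: float, n_doses: int, start: float = 0.0) -> "Regimen":
        if n_doses < 1 or tau <= 0:
            raise ValueError("need n_doses >= 1 and tau > 0")
        return cls(tuple(DoseEvent(amount, start + i * tau) for i in range(n_doses)))

    @classmethod
    def steady_state(cls, amount: float, tau: float, time: float = 0.0) -> "Regimen":
        return cls((DoseEvent(amount, time, ss=True, tau=tau),))


@dataclass(frozen=True)
class ExposureMetrics:
    """Steady-state exposure summary for one dosing stratum."""

    cmax_ss: float
    tmax_ss: float
    cmin_ss: float
    auc_weekly_ss: float

    def __post_init__(self) -> None:
        if not (self.cmax_ss >= self.cmin_ss >= 0):
            raise ValueError("require cmax_ss >= cmin_ss >= 0")
        if not self.auc_weekly_ss > 0:
            raise ValueError("auc_weekly_ss must be > 0")


# ---------------------------------------------------------------------------
# Raw kernels.  No validation; dtype-agnostic (they are reused with complex
# parameters by the estimation engine's complex-step derivatives).  Masks are
# computed from the (always real) time arrays only.
# ---------------------------------------------------------------------------


def _bateman(ka, ke, v, dose, t):
    t = np.asarray(t)
    conc = dose * ka / (v * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
    return np.where(t < 0, 0.0, conc)


def _bateman_equal(ka, v, dose, t):
    t = np.asarray(t)
    conc = dose * ka * t * np.exp(-ka * t) / v
    return np.where(t < 0, 0.0, conc)


def _ss_conc(ka, ke, v, dose, tau, t):
    t = np.asarray(t)
    acc_e = 1.0 - np.exp(-ke * tau)
    acc_a = 1.0 - np.exp(-ka * tau)
    return (
        dose
        * ka
        / (v * (ka - ke))
        * (np.exp(-ke * t) / acc_e - np.exp(-ka * t) / acc_a)
    )


def _ss_conc_equal(ka, v, dose, tau, t):
    # limit ka -> ke of _ss_conc: sum over n of (t + n*tau) exp(-ka (t + n*tau))
    t = np.asarray(t)
    r = np.exp(-ka * tau)
    return dose * ka / v * np.exp(-ka * t) * (t / (1 - r) + tau * r / (1 - r) ** 2)


def _check_degenerate(p: PKParameters, allow_equal_rates: bool) -> bool:
    """Return True when the equal-rates limit form must be used."""
    if p.is_degenerate():
        if not allow_equal_rates:
            raise ValueError(
                f"ka ({p.ka:.6g}) and ke ({p.ke:.6g}) coincide within tolerance; "
                "pass allow_equal_rates=True to use the equal-rates limit form"
            )
        return True
    return False


# ---------------------------------------------------------------------------
# Public concentration functions
# ---------------------------------------------------------------------------


def conc_single_dose(p: PKParameters, dose: float, t, *, allow_equal_rates: bool = False):
    """Concentration (mg/L) after a single oral dose given at t = 0.

    `t` may be a scalar or array of times (h); negative times return 0.
    """
    if not dose > 0:
        raise ValueError("dose must be > 0")
    if _check_degenerate(p, allow_equal_rates):
        out = _bateman_equal(p.ka, p.v, dose, t)
    else:
        out = _bateman(p.ka, p.ke, p.v, dose, t)
    return float(out) if np.ndim(t) == 0 else out


def conc_steady_state(p: PKParameters, dose: float, tau: float, t, *, allow_equal_rates: bool = False):
    """Concentration (mg/L) at steady state under `dose` every `tau` h.

    `t` is time after dose within the interval, 0 <= t <= tau; the profile is
    periodic so t = 0 and t = tau both give the trough.
    """
    if not dose > 0:
        raise ValueError("dose must be > 0")
    if not tau > 0:
        raise ValueError("tau must be > 0")
    tarr = np.asarray(t, dtype=float)
    if np.any(tarr < 0) or np.any(tarr > tau):
        raise ValueError("steady-state times must satisfy 0 <= t <= tau")
    if _check_degenerate(p, allow_equal_rates):
        out = _ss_conc_equal(p.ka, p.v, dose, tau, tarr)
    else:
        out = _ss_conc(p.ka, p.ke, p.v, dose, tau, tarr)
    return float(out) if np.ndim(t) == 0 else out


def conc_profile(
    p: PKParameters,
    regimen: Regimen,
    times: Sequence[float],
    *,
    allow_equal_rates: bool = False,
) -> np.ndarray:
    """Concentration (mg/L) at `times` by superposition over the regimen.

    Steady-state-flagged events contribute the periodic steady-state profile
    (extended periodically beyond one interval); plain events contribute the
    single-dose solution.  An empty `times` returns an empty array.
    """
    times = np.asarray(list(times), dtype=float)
    out = np.zeros_like(times)
    for d in regimen.doses:
        tad = times - d.time
        if d.ss:
            assert d.tau is not None
            contrib = conc_steady_state(
                p, d.amount, d.tau, np.mod(np.maximum(tad, 0.0), d.tau),
                allow_equal_rates=allow_equal_rates,
            )
            out += np.where(tad < 0, 0.0, contrib)
        else:
            out += conc_single_dose(p, d.amount, tad, allow_equal_rates=allow_equal_rates)
    return out


def tmax_steady_state(p: PKParameters, tau: float) -> float:
    """Time of the steady-state concentration peak within a dosing interval.

    Closed-form stationary point of the periodic profile:
    t* = ln[ka (1 - e^(-ke tau)) / (ke (1 - e^(-ka tau)))] / (ka - ke).
    """
    if not tau > 0:
        raise ValueError("tau must be > 0")
    _check_degenerate(p, False)
    ka, ke = p.ka, p.ke
    num = ka * (1.0 - math.exp(-ke * tau))
    den = ke * (1.0 - math.exp(-ka * tau))
    return math.log(num / den) / (ka - ke)


def exposure_metrics(
    p: PKParameters,
    dose: float,
    tau: float,
    weekly_dose: float | None = None,
) -> ExposureMetrics:
    """Steady-state exposure metrics under `dose` every `tau` hours.

    Cmax,ss and its time come from the closed-form stationary point, Cmin,ss
    is the interval-boundary (trough) value, and AUC_weekly,ss is the exact
    linear-kinetics value weekly_dose / CL.  `weekly_dose` defaults to
    dose * 168 / tau.
    """
    if weekly_dose is None:
        weekly_dose = dose * 168.0 / tau
    tmax = tmax_steady_state(p, tau)
    cmax = conc_steady_state(p, dose, tau, tmax)
    cmin = conc_steady_state(p, dose, tau, 0.0)
    auc = weekly_dose / p.cl
    return ExposureMetrics(cmax_ss=cmax, tmax_ss=tmax, cmin_ss=cmin, auc_weekly_ss=auc)
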