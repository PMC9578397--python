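"""Independent numerical oracles used by the tests.

These deliberately avoid the package's closed-form/Laplace code paths:
concentrations come from Runge-Kutta integration of the two-state
absorption/disposition ODE system, and marginal likelihoods from dense
mode-centred Gauss-Hermite quadrature with independently computed modes.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.integrate import solve_ivp
from scipy.optimize import minimize


def ode_concentration(ka, cl, v, dose, times, n_doses=1, tau=None):
    """Concentration profile by ODE integration over repeated dosing.

    States: amount in gut, amount in central compartment.  Doses are added
    to the gut at multiples of tau (first dose at t=0).
    """
    ke = cl / v
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if n_doses > 1 and tau is None:
        raise ValueError("tau required for repeated dosing")

    def rhs(t, y):
        return [-ka * y[0], ka * y[0] - ke * y[1]]

    t_end = float(times.max()) if n_doses == 1 else (n_doses - 1) * tau + float(times.max())
    y = np.array([dose, 0.0])
    out = np.zeros_like(times)
    segments = [0.0] + [i * tau for i in range(1, n_doses)] + [t_end + 1e-9]
    all_t = []
    all_c = []
    for i in range(len(segments) - 1):
        t0, t1 = segments[i], segments[i + 1]
        sol = solve_ivp(rhs, (t0, t1), y, rtol=1e-10, atol=1e-12, dense_output=True)
        all_t.append((t0, t1, sol.sol))
        y = sol.y[:, -1].copy()
        if i + 1 < len(segments) - 1:
            y[0] += dose
    # evaluate at requested times measured from the LAST dose
    t_offset = (n_doses - 1) * tau if n_doses > 1 else 0.0
    for j, t in enumerate(times):
        tq = t + t_offset
        for t0, t1, interp in all_t:
            if t0 - 1e-12 <= tq <= t1 + 1e-12:
                out[j] = interp(min(max(tq, t0), t1))[1] / v
                break
    return out


def exact_marginal_m2ll(qfun, k, n_nodes=81, n_starts=9, seed=0):
    """-2 log of the exact marginal likelihood by adaptive Gauss-Hermite.

    qfun(eta) must return the joint -2 log density of (data, eta).  The mode
    is located by multi-start Nelder-Mead; the quadrature grid is centred
    and scaled by a finite-difference Hessian at the mode.
    """
    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        x0 = np.zeros(k) if s == 0 else rng.normal(size=k) * 1.5
        r = minimize(qfun, x0, method="Nelder-Mead", options={"xatol": 1e-11, "fatol": 1e-13})
        if best is None or r.fun < best.fun:
            best = r
    mode, qmin = best.x, best.fun
    h = 1e-4
    H = np.zeros((k, k))
    eye = np.eye(k)
    for i in range(k):
        for j in range(k):
            ei, ej = eye[i] * h, eye[j] * h
            H[i, j] = (
                qfun(mode + ei + ej) - qfun(mode + ei - ej) - qfun(mode - ei + ej) + qfun(mode - ei - ej)
            ) / (4 * h * h)
    L = np.linalg.cholesky(np.linalg.inv(H / 2.0))
    z, w = hermegauss(n_nodes)
    grids = np.meshgrid(*([z] * k), indexing="ij")
    zs = np.stack([g.ravel() for g in grids], axis=1)
    ws = np.ones(len(zs))
    for g in np.meshgrid(*([w] * k), indexing="ij"):
        ws = ws * g.ravel()
    total = 0.0
    for zz, ww in zip(zs, ws):
        eta = mode + L @ zz
        total += ww * math.exp(-(qfun(eta) - qmin) / 2.0 + float(zz @ zz) / 2.0)
    return -2.0 * (math.log(total) + float(np.linalg.slogdet(L)[1]) - qmin / 2.0)
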