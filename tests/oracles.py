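"""Independent oracles used by the test suite.

These deliberately avoid the package's computational paths: the ODE
oracle integrates the absorption/elimination system numerically, and the
likelihood oracle evaluates its own closed-form predictions and
integrates the random effects on a dense tensor grid.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from tacpk.core_model import PKParameters, PopulationModel, typical_values
from tacpk.io import Dataset


def ode_profile(params: PKParameters, doses, times) -> np.ndarray:
    """Concentrations (ng/ml) by numerical integration of the ODE system.

    States: gut amount and central amount (mg); each dose is an impulse
    into the gut. Integrated segment-by-segment between events.
    """
    ka, ke, v = params.ka, params.cl_f / params.v_f, params.v_f

    def rhs(_t, y):
        return [-ka * y[0], ka * y[0] - ke * y[1]]

    obs_times = [float(t) for t in times]
    events = sorted({d.time for d in doses} | set(obs_times))
    dose_at: dict[float, float] = {}
    for d in doses:
        dose_at[d.time] = dose_at.get(d.time, 0.0) + d.amount
    y = np.zeros(2)
    t_prev = 0.0
    out = {}
    for t in events:
        if t > t_prev:
            sol = solve_ivp(rhs, (t_prev, t), y, rtol=1e-11, atol=1e-14,
                            method="LSODA")
            y = sol.y[:, -1]
            t_prev = t
        # an observation at t is read BEFORE any dose at t (pre-dose trough)
        if t in set(obs_times):
            out[t] = y[1] / v * 1000.0
        if t in dose_at:
            y = y.copy()
            y[0] += dose_at[t]
    return np.array([out.get(t, 0.0) for t in obs_times])


def _oracle_predict(cl, v, ka, dose_times, amounts, obs_times):
    """Closed-form superposition, vectorized over (cl, v) pairs.

    cl, v: arrays (G,); returns (G, n_obs). Written independently of the
    package's prediction code (straight from the textbook solution).
    """
    cl = np.atleast_1d(np.asarray(cl, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    ke = cl / v  # (G,)
    dt = np.asarray(obs_times)[:, None] - np.asarray(dose_times)[None, :]
    mask = dt > 0
    dt = np.where(mask, dt, 0.0)
    ek = np.exp(-ke[:, None, None] * dt[None, :, :])
    ea = np.exp(-ka * dt)[None, :, :]
    coef = (ka / (v * (ka - ke)))[:, None, None]
    terms = np.where(mask[None, :, :], coef * (ek - ea), 0.0)
    conc = (terms * np.asarray(amounts)[None, None, :]).sum(axis=2)
    return conc * 1000.0


def quadrature_ofv(
    dataset: Dataset,
    model: PopulationModel,
    span: float = 6.0,
    n_points: int = 401,
    chunk: int = 4096,
) -> float:
    """-2 log marginal likelihood minus n*log(2*pi), by dense-grid quadrature.

    The eta integral per subject runs over a tensor grid of +/- span
    standard deviations per active dimension (trapezoid rule in each).
    Matches the NONMEM OFV convention of dropping the 2*pi constants.
    """
    s1sq, s2sq = model.sigma_prop**2, model.sigma_add**2
    omegas = np.array([model.omega_cl, model.omega_v])
    active = [d for d in range(2) if omegas[d] > 1e-10]

    total = 0.0
    for sd in dataset.subjects():
        tv = typical_values(model, sd.weight, sd.covariates)
        y = sd.obs_dv

        def neg2_datum(eta1, eta2):
            """-2 log p(y|eta) - n log 2pi for flat eta arrays."""
            out = np.empty(eta1.size)
            for lo in range(0, eta1.size, chunk):
                sl = slice(lo, lo + chunk)
                f = _oracle_predict(
                    tv[0] * np.exp(eta1[sl]), tv[1] * np.exp(eta2[sl]),
                    model.ka_fixed, sd.dose_times, sd.dose_amounts,
                    sd.obs_times,
                )
                var = f * f * s1sq + s2sq
                out[sl] = ((y[None, :] - f) ** 2 / var + np.log(var)).sum(axis=1)
            return out

        if not active:
            total += float(neg2_datum(np.zeros(1), np.zeros(1))[0])
            continue

        grids = {d: np.linspace(-span * omegas[d], span * omegas[d], n_points)
                 for d in active}
        if len(active) == 1:
            d = active[0]
            g = grids[d]
            e1 = g if d == 0 else np.zeros_like(g)
            e2 = g if d == 1 else np.zeros_like(g)
            logp = -0.5 * (neg2_datum(e1, e2)
                           + g**2 / omegas[d] ** 2 + np.log(omegas[d] ** 2))
            log_int = _log_trapz(logp, g)
            total += -2.0 * log_int + np.log(2.0 * np.pi)
        else:
            g1, g2 = grids[0], grids[1]
            E1, E2 = np.meshgrid(g1, g2, indexing="ij")
            vals = neg2_datum(E1.ravel(), E2.ravel()).reshape(n_points, n_points)
            vals = vals + (E1**2 / omegas[0] ** 2 + np.log(omegas[0] ** 2)
                           + E2**2 / omegas[1] ** 2 + np.log(omegas[1] ** 2))
            logp = -0.5 * vals
            inner = np.array([_log_trapz(logp[i], g2) for i in range(n_points)])
            log_int = _log_trapz(inner, g1)
            total += -2.0 * log_int + 2.0 * np.log(2.0 * np.pi)
    return total


def _log_trapz(log_vals: np.ndarray, grid: np.ndarray) -> float:
    """log of the trapezoid integral of exp(log_vals) over grid."""
    m = float(np.max(log_vals))
    return m + float(np.log(np.trapezoid(np.exp(log_vals - m), grid)))
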