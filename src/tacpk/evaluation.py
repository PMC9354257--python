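"""Goodness-of-fit diagnostics and nonparametric bootstrap validation.

Diagnostics emit one row per observation with population and individual
predictions and the two weighted-residual flavors (iWRES, CWRES) as a
plain data table; plotting is deliberately left to callers. The
bootstrap resamples subjects with replacement, refits each replicate and
summarizes parameters by median, 2.5th/97.5th percentiles and the bias
formula (median - estimate) / estimate * 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import PopulationModel
from .estimation import FitResult, _jacobian, _SubjectWork, _typical_for, fit
from .io import Dataset

__all__ = [
    "DiagnosticsError",
    "BootstrapResult",
    "diagnostics",
    "bootstrap",
    "bias_percent",
]

#: parameters summarized by the bootstrap
_BOOT_PARAMS = ("tv_cl", "tv_v", "omega_cl", "omega_v", "sigma_prop", "sigma_add")


class DiagnosticsError(RuntimeError):
    pass


def bias_percent(estimate: float, median: float) -> float:
    """Bootstrap bias, (median - estimate) / estimate * 100, to 3 decimals."""
    if estimate == 0:
        raise ValueError("bias is undefined for a zero estimate")
    return round((median - estimate) / estimate * 100.0, 3)


def diagnostics(dataset: Dataset, result: FitResult) -> pd.DataFrame:
    """Per-observation diagnostics table (ID, TIME, DV, PRED, IPRED, iWRES, CWRES).

    PRED is the model prediction at eta = 0, IPRED at the post-hoc mode;
    iWRES = (DV - IPRED) / sqrt(IPRED^2 s1^2 + s2^2); CWRES whitens the
    observed-minus-population-linearized residual with the subject-level
    covariance from the first-order expansion at eta-hat.
    """
    if not result.converged:
        raise DiagnosticsError("diagnostics require a converged fit")
    model = result.estimates
    s1sq, s2sq = model.sigma_prop**2, model.sigma_add**2
    if s1sq <= 0 and s2sq <= 0:
        raise DiagnosticsError("residual variance is identically zero")

    rows = []
    for sd in dataset.subjects():
        work = _SubjectWork(sd, model.ka_fixed)
        tv = _typical_for(model, sd)
        eta_hat = result.post_hoc_etas[sd.subject_id].as_array()

        pred = work.predict(tv[0], tv[1], model.ka_fixed)
        cl_i = tv[0] * np.exp(eta_hat[0])
        v_i = tv[1] * np.exp(eta_hat[1])
        ipred = work.predict(cl_i, v_i, model.ka_fixed)

        ivar = np.maximum(ipred**2 * s1sq + s2sq, 1e-12)
        iwres = (sd.obs_dv - ipred) / np.sqrt(ivar)

        idx = [0, 1]
        J = _jacobian(work, tv, model.ka_fixed, eta_hat, idx)
        omega = np.diag([model.omega_cl**2, model.omega_v**2])
        V = J @ omega @ J.T + np.diag(ivar)
        r = sd.obs_dv - ipred + J @ eta_hat
        L = np.linalg.cholesky(V)
        cwres = np.linalg.solve(L, r)

        for j in range(work.n):
            rows.append({
                "ID": sd.subject_id,
                "TIME": float(sd.obs_times[j]),
                "DV": float(sd.obs_dv[j]),
                "PRED": float(pred[j]),
                "IPRED": float(ipred[j]),
                "iWRES": float(iwres[j]),
                "CWRES": float(cwres[j]),
            })
    return pd.DataFrame(rows)


@dataclass
class BootstrapResult:
    """Summary of a subject-resampling bootstrap."""

    table: pd.DataFrame  # parameter, estimate, median, ci_low, ci_high, bias_percent
    n_requested: int
    n_converged: int
    replicates: pd.DataFrame  # one row of parameter values per converged replicate
    warning: str | None = None

    @property
    def failure_fraction(self) -> float:
        return 1.0 - self.n_converged / self.n_requested if self.n_requested else 0.0


def bootstrap(
    dataset: Dataset,
    start: PopulationModel,
    n: int,
    rng: np.random.Generator | int | None = None,
    *,
    original: FitResult | None = None,
    fit_kwargs: dict | None = None,
) -> BootstrapResult:
    """Resample subjects with replacement ``n`` times and refit each replicate.

    ``original`` supplies the point estimates the bias is computed
    against (fitted from scratch when omitted). Non-converged replicates
    are excluded from the summaries and counted; >20% failures sets a
    warning on the result.
    """
    if n < 1:
        raise ValueError("bootstrap requires n >= 1")
    if not hasattr(rng, "integers"):  # accept any Generator-like source
        rng = np.random.default_rng(rng)
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("compute_se", False)

    if original is None:
        original = fit(dataset, start, **{**fit_kwargs, "compute_se": False})
    est = {p: getattr(original.estimates, p) for p in _BOOT_PARAMS}

    ids = dataset.subject_ids
    rep_rows = []
    n_converged = 0
    for _ in range(n):
        draw = [ids[k] for k in rng.integers(0, len(ids), size=len(ids))]
        resampled = dataset.subset(draw, relabel=True)
        try:
            r = fit(resampled, start, **fit_kwargs)
        except Exception:
            continue
        if not r.converged:
            continue
        n_converged += 1
        rep_rows.append({p: getattr(r.estimates, p) for p in _BOOT_PARAMS})

    reps = pd.DataFrame(rep_rows, columns=list(_BOOT_PARAMS))
    rows = []
    for p in _BOOT_PARAMS:
        vals = reps[p].to_numpy()
        if vals.size:
            med = float(np.median(vals))
            lo, hi = (float(v) for v in np.percentile(vals, [2.5, 97.5]))
            bias = bias_percent(est[p], med) if est[p] != 0 else float("nan")
        else:
            med = lo = hi = bias = float("nan")
        rows.append({"parameter": p, "estimate": est[p], "median": med,
                     "ci_low": lo, "ci_high": hi, "bias_percent": bias})
    table = pd.DataFrame(rows)

    warning = None
    frac_failed = 1.0 - n_converged / n
    if frac_failed > 0.2:
        warning = f"{frac_failed:.0%} of bootstrap replicates failed to converge"
    return BootstrapResult(table, n, n_converged, reps, warning)
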