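"""One-compartment oral-absorption pharmacokinetic kernel.

Closed-form concentration profiles under multiple dosing, allometric
body-weight scaling of the typical parameters, log-normal between-subject
variability and a combined (proportional + additive) residual-error model.
Every other layer of the package — simulation, likelihood, dose
optimization — is built on the functions in this module.

Units
-----
Internal computation uses mg (dose amounts), L (volumes) and h (times).
Amount/volume gives mg/L; whole-blood tacrolimus concentrations are
reported in ng/ml, and 1 mg/L = 1000 ug/L = 1000 ng/ml, so profiles are
multiplied by 1000 exactly once, at the end of :func:`concentration_profile`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PKParameters",
    "PopulationModel",
    "RandomEffects",
    "DoseEvent",
    "Observation",
    "CovariateEffect",
    "MGL_TO_NGML",
    "typical_clearance",
    "typical_volume",
    "typical_values",
    "individual_params",
    "concentration_profile",
    "unit_dose_profile",
    "apply_residual_error",
    "residual_variance",
    "final_model",
]

#: conversion factor mg/L -> ng/ml (1 mg/L = 1000 ug/L; 1 ug/L = 1 ng/ml)
MGL_TO_NGML = 1000.0

#: |ka - ke| * t below this switches to the analytic ka == ke limit branch
_KE_KA_TOL = 1e-9


@dataclass(frozen=True)
class PKParameters:
    """Individual apparent PK parameters.

    cl_f
        Apparent clearance CL/F, L/h.
    v_f
        Apparent volume of distribution V/F, L.
    ka
        First-order absorption rate constant, 1/h.
    """

    cl_f: float
    v_f: float
    ka: float

    def __post_init__(self) -> None:
        if not (self.cl_f > 0 and self.v_f > 0 and self.ka > 0):
            raise ValueError(
                f"PK parameters must be strictly positive, got "
                f"cl_f={self.cl_f}, v_f={self.v_f}, ka={self.ka}"
            )

    @property
    def ke(self) -> float:
        """Elimination rate constant CL/F / V/F, 1/h."""
        return self.cl_f / self.v_f


@dataclass(frozen=True)
class RandomEffects:
    """Subject-level random deviations (eta) on log CL/F and log V/F."""

    eta_cl: float = 0.0
    eta_v: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.eta_cl) and math.isfinite(self.eta_v)):
            raise ValueError("random effects must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.eta_cl, self.eta_v])


@dataclass(frozen=True)
class DoseEvent:
    """A single oral dose: time in hours since first dose, amount in mg."""

    time: float
    amount: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.amount <= 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")


@dataclass(frozen=True)
class Observation:
    """An observed whole-blood concentration: time h, concentration ng/ml."""

    time: float
    concentration: float
    below_assay: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"observation time must be >= 0, got {self.time}")
        if self.concentration < 0:
            raise ValueError("observed concentration must be >= 0")


@dataclass(frozen=True)
class CovariateEffect:
    """A covariate-parameter relation on top of the allometric base.

    ``form`` is ``"power"`` for continuous covariates,
    ``T * (cov / cov_median) ** theta``, or ``"linear"`` for categorical
    covariates, ``T * (1 + theta * cov)``.
    """

    parameter: str  # "cl" or "v"
    covariate: str
    form: str  # "power" | "linear"
    theta: float
    cov_median: float | None = None

    def __post_init__(self) -> None:
        if self.parameter not in ("cl", "v"):
            raise ValueError(f"parameter must be 'cl' or 'v', got {self.parameter!r}")
        if self.form not in ("power", "linear"):
            raise ValueError(f"form must be 'power' or 'linear', got {self.form!r}")
        if self.form == "power" and (self.cov_median is None or self.cov_median <= 0):
            raise ValueError("power form requires a positive cov_median")

    def factor(self, value: float) -> float:
        if self.form == "power":
            if value <= 0:
                raise ValueError(
                    f"power-form covariate {self.covariate!r} requires a "
                    f"positive value, got {value}"
                )
            return (value / self.cov_median) ** self.theta
        return 1.0 + self.theta * value


@dataclass(frozen=True)
class PopulationModel:
    """The full generative population model.

    Fixed effects are the typical CL/F and V/F at the reference body
    weight, scaled allometrically to each subject's weight; ka is fixed.
    ``omega_*`` are standard deviations of the log-normal between-subject
    random effects; ``sigma_prop``/``sigma_add`` the standard deviations
    of the proportional and additive residual components.
    """

    tv_cl: float = 13.1  # L/h at ref_weight
    tv_v: float = 10900.0  # L at ref_weight
    ka_fixed: float = 4.48  # 1/h
    ref_weight: float = 70.0  # kg
    exp_cl: float = 0.75
    exp_v: float = 1.0
    omega_cl: float = 0.451
    omega_v: float = 0.592
    sigma_prop: float = 0.257
    sigma_add: float = 1.265  # ng/ml
    covariate_effects: tuple[CovariateEffect, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.tv_cl > 0 and self.tv_v > 0 and self.ka_fixed > 0):
            raise ValueError("tv_cl, tv_v and ka_fixed must be strictly positive")
        if self.ref_weight <= 0:
            raise ValueError("ref_weight must be strictly positive")
        if min(self.omega_cl, self.omega_v, self.sigma_prop, self.sigma_add) < 0:
            raise ValueError("omega and sigma values must be >= 0")
        if not (math.isfinite(self.exp_cl) and math.isfinite(self.exp_v)):
            raise ValueError("allometric exponents must be finite")
        object.__setattr__(self, "covariate_effects", tuple(self.covariate_effects))

    def with_updates(self, **kwargs) -> "PopulationModel":
        return replace(self, **kwargs)

    @property
    def omega_matrix(self) -> np.ndarray:
        """Diagonal between-subject covariance matrix (no CL-V correlation)."""
        return np.diag([self.omega_cl**2, self.omega_v**2])


def final_model() -> PopulationModel:
    """The published final model: CL/F = 13.1*(WT/70)^0.75, V/F = 10900*(WT/70)."""
    return PopulationModel()


def _check_weight(weight: float) -> None:
    if not weight > 0:
        raise ValueError(f"body weight must be strictly positive, got {weight}")


def typical_clearance(model: PopulationModel, weight: float) -> float:
    """Typical CL/F (L/h) at ``weight`` kg via fixed allometry."""
    _check_weight(weight)
    return model.tv_cl * (weight / model.ref_weight) ** model.exp_cl


def typical_volume(model: PopulationModel, weight: float) -> float:
    """Typical V/F (L) at ``weight`` kg via fixed allometry."""
    _check_weight(weight)
    return model.tv_v * (weight / model.ref_weight) ** model.exp_v


def typical_values(
    model: PopulationModel,
    weight: float,
    covariates: dict[str, float] | None = None,
) -> tuple[float, float]:
    """Typical (CL/F, V/F) including any estimated covariate effects.

    The allometric weight terms are always applied; additional covariate
    effects multiply on top, each evaluated on the subject's covariate value.
    """
    cl = typical_clearance(model, weight)
    v = typical_volume(model, weight)
    for eff in model.covariate_effects:
        value = (covariates or {}).get(eff.covariate)
        if value is None:
            raise KeyError(
                f"model requires covariate {eff.covariate!r} which is missing"
            )
        if eff.parameter == "cl":
            cl *= eff.factor(value)
        else:
            v *= eff.factor(value)
    return cl, v


def individual_params(
    model: PopulationModel,
    weight: float,
    eta: RandomEffects,
    covariates: dict[str, float] | None = None,
) -> PKParameters:
    """Individual parameters: typical values times exp(eta), ka fixed."""
    cl, v = typical_values(model, weight, covariates)
    return PKParameters(
        cl_f=cl * math.exp(eta.eta_cl),
        v_f=v * math.exp(eta.eta_v),
        ka=model.ka_fixed,
    )


def unit_dose_profile(
    params: PKParameters,
    dose_times: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Concentration (ng/ml) at ``times`` for 1 mg given at each dose time.

    Superposition of the closed-form one-compartment first-order
    absorption solution; doses in the future of an evaluation time
    contribute zero, as does a dose given exactly at the evaluation time
    (trough convention: sample drawn immediately pre-dose).

    Being exactly linear in the dose amounts, the full profile for any
    amounts vector ``amt`` is ``unit_dose_profile(...) @ amt``-style
    scaling; :func:`concentration_profile` does that weighting.
    """
    dose_times = np.asarray(dose_times, dtype=float)
    times = np.asarray(times, dtype=float)
    ka = params.ka
    ke = params.ke

    # dt[i, j] = elapsed time from dose j to observation i
    dt = times[:, None] - dose_times[None, :]
    active = dt > 0.0
    dt = np.where(active, dt, 0.0)

    if abs(ka - ke) * max(float(np.max(dt, initial=0.0)), 1.0) < _KE_KA_TOL:
        # ka -> ke limit: C(t) = D * ka * t / V * exp(-ka t)
        terms = ka * dt / params.v_f * np.exp(-ka * dt)
    else:
        scale = ka / (params.v_f * (ka - ke))
        terms = scale * (np.exp(-ke * dt) - np.exp(-ka * dt))
    terms = np.where(active, terms, 0.0)
    return terms.sum(axis=1) * MGL_TO_NGML


def concentration_profile(
    params: PKParameters,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
) -> np.ndarray:
    """Predicted concentrations (ng/ml) at ``times`` under a dosing history.

    Amounts in mg, volume in L; the mg/L result is converted to ng/ml.
    """
    times_arr = np.asarray(list(times), dtype=float)
    if np.any(times_arr < 0):
        raise ValueError("evaluation times must be >= 0")
    if len(doses) == 0:
        return np.zeros_like(times_arr)
    dose_times = np.array([d.time for d in doses], dtype=float)
    amounts = np.array([d.amount for d in doses], dtype=float)

    ka = params.ka
    ke = params.ke
    dt = times_arr[:, None] - dose_times[None, :]
    active = dt > 0.0
    dt = np.where(active, dt, 0.0)
    if abs(ka - ke) * max(float(np.max(dt, initial=0.0)), 1.0) < _KE_KA_TOL:
        terms = ka * dt / params.v_f * np.exp(-ka * dt)
    else:
        scale = ka / (params.v_f * (ka - ke))
        terms = scale * (np.exp(-ke * dt) - np.exp(-ka * dt))
    terms = np.where(active, terms, 0.0)
    return (terms * amounts[None, :]).sum(axis=1) * MGL_TO_NGML


def residual_variance(model: PopulationModel, pred: np.ndarray) -> np.ndarray:
    """Residual variance at prediction(s): pred^2 * sigma1^2 + sigma2^2."""
    pred = np.asarray(pred, dtype=float)
    return pred**2 * model.sigma_prop**2 + model.sigma_add**2


def apply_residual_error(
    model: PopulationModel,
    pred: float | np.ndarray,
    eps: tuple[float, float] | np.ndarray,
) -> float | np.ndarray:
    """Observed = pred * (1 + eps1) + eps2 (combined residual-error model).

    Negative outputs are possible through the additive term and are NOT
    clamped here; clamping happens only at reporting/simulation layers.
    """
    pred = np.asarray(pred, dtype=float)
    if np.any(pred < 0):
        raise ValueError("model predictions must be >= 0")
    eps1, eps2 = eps[0], eps[1]
    out = pred * (1.0 + np.asarray(eps1)) + np.asarray(eps2)
    return float(out) if out.ndim == 0 else out
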