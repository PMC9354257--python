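"""Virtual cohort generator for pediatric SCID-HSCT tacrolimus studies.

Builds cohorts with the demographic and sampling structure of the study
population (18 infants, body weight median 7.50 kg range 4.20-12.60 kg,
about 7.2 trough concentrations per subject, twice-daily oral dosing) so
that estimation, validation and simulation can be exercised without
patient data. The generative model is the population model itself:
log-normal eta on CL/F and V/F, combined residual error on each trough.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    DoseEvent,
    Observation,
    PopulationModel,
    RandomEffects,
    apply_residual_error,
    individual_params,
    unit_dose_profile,
)
from .io import Dataset

__all__ = ["CohortSpec", "Subject", "sample_demographics", "simulate_cohort",
           "CONTINUOUS_COVARIATES", "COMEDICATION_COUNTS"]

#: continuous covariate -> (mean, sd, low, high); cohort-defining defaults
CONTINUOUS_COVARIATES: dict[str, tuple[float, float, float, float]] = {
    "AGE": (0.82, 0.56, 0.33, 3.01),          # years
    "ALB": (32.76, 3.66, 25.10, 40.80),       # albumin g/L
    "ALT": (38.12, 38.05, 11.00, 140.10),     # IU/L
    "AST": (61.96, 31.48, 29.30, 152.00),     # IU/L
    "CREA": (17.72, 3.79, 9.00, 27.00),       # umol/L
    "UREA": (2.77, 1.64, 0.60, 7.00),         # mmol/L
    "TP": (57.30, 7.35, 46.80, 75.40),        # total protein g/L
    "TBA": (7.08, 5.33, 0.10, 21.30),         # total bile acid umol/L
    "DBIL": (4.28, 5.53, 0.80, 24.40),        # direct bilirubin umol/L
    "TBIL": (8.79, 8.53, 2.20, 39.70),        # total bilirubin umol/L
    "HCT": (29.13, 7.50, 22.80, 53.31),       # hematocrit %
    "HGB": (93.58, 24.48, 69.00, 167.00),     # hemoglobin g/L
    "MCH": (25.28, 4.16, 19.00, 33.30),       # pg
    "MCHC": (321.00, 19.56, 289.00, 366.00),  # g/L
}

#: comedication flag -> count among the 18 reference subjects
COMEDICATION_COUNTS: dict[str, int] = {
    "CASPOFUNGIN": 9,
    "ETHAMBUTOL": 10,
    "GLUCOCORTICOIDS": 17,
    "ISONIAZIDE": 14,
    "MICAFUNGIN": 9,
    "MYCOPHENOLATE": 6,
    "OMEPRAZOLE": 13,
    "VANCOMYCIN": 10,
}

#: reference cohort size the comedication counts refer to
_REF_N = 18

#: assay quantification window, ng/ml
ASSAY_RANGE = (2.0, 30.0)


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort.

    Sampling days give the default trough schedule (7 per subject); when
    ``obs_per_subject_mean`` exceeds their count, extra days are drawn per
    subject from ``extra_day_pool`` with the matching probability so the
    expected count hits the target (7.2 by default -> about 130 troughs
    across 18 subjects). The actual pre-titration dose level received by
    the reference patients is never reported; 0.3 mg/kg/day is an assumed
    default, configurable.
    """

    n_subjects: int = 18
    weight_median: float = 7.50
    weight_range: tuple[float, float] = (4.20, 12.60)
    weight_cv: float = 0.2226  # lognormal CV matching mean 7.28 / sd 1.62
    obs_per_subject_mean: float = 7.2
    dose_per_kg: float = 0.3  # mg/kg/day, split into two doses
    dosing_interval: float = 12.0  # h
    sampling_days: tuple[int, ...] = (2, 4, 6, 8, 10, 13, 15)
    extra_day_pool: tuple[int, ...] = (3, 5, 7, 9, 11, 12, 14)
    include_covariates: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        lo, hi = self.weight_range
        if not lo < hi:
            raise ValueError("weight_range must satisfy low < high")
        if not (lo <= self.weight_median <= hi):
            raise ValueError(
                f"weight median {self.weight_median} outside range {self.weight_range}"
            )
        if self.obs_per_subject_mean < 1:
            raise ValueError("obs_per_subject_mean must be >= 1")
        if self.dose_per_kg <= 0:
            raise ValueError("dose_per_kg must be > 0")
        if self.obs_per_subject_mean > len(self.sampling_days) + len(self.extra_day_pool):
            raise ValueError("obs_per_subject_mean exceeds available sampling days")


@dataclass
class Subject:
    """One virtual patient, with the generative eta retained for recovery tests."""

    subject_id: str
    weight: float
    covariates: dict[str, float] = field(default_factory=dict)
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)
    true_eta: RandomEffects | None = None


def _truncated_lognormal(
    rng: np.random.Generator, median: float, cv: float, low: float, high: float
) -> float:
    """Rejection-sample a lognormal with given median/CV truncated to [low, high]."""
    mu = math.log(median)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    for _ in range(10_000):
        x = float(rng.lognormal(mu, sigma))
        if low <= x <= high:
            return x
    raise RuntimeError("truncated lognormal sampling failed to accept")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float
) -> float:
    for _ in range(10_000):
        x = float(rng.normal(mean, sd))
        if low <= x <= high:
            return x
    # pathological spec (range far from mean): fall back to uniform
    return float(rng.uniform(low, high))


def sample_demographics(spec: CohortSpec, rng: np.random.Generator) -> list[Subject]:
    """Draw subjects' weights and covariates (no dosing/observations yet)."""
    subjects = []
    for i in range(spec.n_subjects):
        weight = _truncated_lognormal(
            rng, spec.weight_median, spec.weight_cv, *spec.weight_range
        )
        covs: dict[str, float] = {}
        if spec.include_covariates:
            for name, (mean, sd, low, high) in CONTINUOUS_COVARIATES.items():
                covs[name] = round(_truncated_normal(rng, mean, sd, low, high), 3)
            for name, count in COMEDICATION_COUNTS.items():
                covs[name] = float(rng.random() < count / _REF_N)
        subjects.append(
            Subject(subject_id=f"S{i + 1:03d}", weight=round(weight, 2), covariates=covs)
        )
    return subjects


def _sampling_days_for_subject(spec: CohortSpec, rng: np.random.Generator) -> list[int]:
    days = list(spec.sampling_days)
    extra_target = spec.obs_per_subject_mean - len(days)
    if extra_target > 0 and spec.extra_day_pool:
        n_extra_base = int(extra_target)
        frac = extra_target - n_extra_base
        n_extra = n_extra_base + (1 if rng.random() < frac else 0)
        pool = [d for d in spec.extra_day_pool if d not in days]
        n_extra = min(n_extra, len(pool))
        if n_extra:
            days += list(rng.choice(pool, size=n_extra, replace=False))
    elif extra_target < 0:
        keep = int(round(spec.obs_per_subject_mean))
        days = sorted(rng.choice(days, size=keep, replace=False))
    return sorted(days)


def simulate_cohort(
    spec: CohortSpec,
    model: PopulationModel,
    rng: np.random.Generator | int | None = None,
) -> tuple[Dataset, list[Subject]]:
    """Simulate a full cohort and return (Dataset, subjects-with-truth).

    Each subject receives ``weight * dose_per_kg / 2`` mg every
    ``dosing_interval`` hours through the last sampling day; troughs are
    drawn immediately pre-dose on that subject's sampling days and
    perturbed with the combined residual-error model. Values that land
    below zero are clamped to 0; values below the assay lower limit are
    flagged (``BLQ``), never dropped.
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(spec.seed if rng is None else rng)

    subjects = sample_demographics(spec, rng)
    rows = []
    for subj in subjects:
        eta = RandomEffects(
            eta_cl=float(rng.normal(0.0, model.omega_cl)),
            eta_v=float(rng.normal(0.0, model.omega_v)),
        )
        subj.true_eta = eta
        params = individual_params(model, subj.weight, eta, subj.covariates)

        days = _sampling_days_for_subject(spec, rng)
        last_time = 24.0 * max(days)
        dose_amount = subj.weight * spec.dose_per_kg / 2.0
        dose_times = np.arange(0.0, last_time + 1e-9, spec.dosing_interval)
        subj.doses = [DoseEvent(t, dose_amount) for t in dose_times]

        obs_times = np.array([24.0 * d for d in days], dtype=float)
        pred = unit_dose_profile(params, dose_times, obs_times) * dose_amount
        eps1 = rng.normal(0.0, model.sigma_prop, size=pred.size)
        eps2 = rng.normal(0.0, model.sigma_add, size=pred.size)
        dv = apply_residual_error(model, pred, (eps1, eps2))
        dv = np.maximum(dv, 0.0)  # clamp at the reporting layer only
        subj.observations = [
            Observation(float(t), float(c), below_assay=bool(c < ASSAY_RANGE[0]))
            for t, c in zip(obs_times, dv)
        ]
        rows.extend(_subject_rows(subj))

    columns = ["ID", "TIME", "AMT", "EVID", "MDV", "DV", "WT", "BLQ"]
    columns += list(subjects[0].covariates.keys())
    return Dataset(pd.DataFrame(rows, columns=columns)), subjects


def _subject_rows(subj: Subject) -> list[dict]:
    events = [("obs", o.time, o) for o in subj.observations]
    events += [("dose", d.time, d) for d in subj.doses]
    # stable sort: at equal times the trough (pre-dose draw) precedes the dose
    events.sort(key=lambda e: (e[1], 0 if e[0] == "obs" else 1))
    rows = []
    for kind, time, ev in events:
        base = {"ID": subj.subject_id, "TIME": time, "WT": subj.weight, **subj.covariates}
        if kind == "dose":
            rows.append({**base, "AMT": ev.amount, "EVID": 1, "MDV": 1,
                         "DV": np.nan, "BLQ": 0})
        else:
            rows.append({**base, "AMT": 0.0, "EVID": 0, "MDV": 0,
                         "DV": round(ev.concentration, 6),
                         "BLQ": int(ev.below_assay)})
    return rows
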