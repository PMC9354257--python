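"""NONMEM-layout dataset container, reader/writer and summary.

The on-disk format is a comma-separated table with a mandatory header and
the standard pharmacometric event columns::

    ID, TIME, AMT, EVID, MDV, DV, WT [, free covariate columns...]

``EVID=1`` rows are doses (AMT > 0, MDV=1, DV missing); ``EVID=0`` rows
are observations (DV in ng/ml unless MDV=1). ``"."`` denotes a missing
value (NONMEM convention) and maps to MDV=1 for DV. TIME is hours since
each subject's first dose. Optional ``BLQ`` column flags simulated values
that fell below the assay range before clamping.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = ["Dataset", "SubjectData", "DatasetError", "read_dataset", "write_dataset", "summarize"]

REQUIRED_COLUMNS = ["ID", "TIME", "AMT", "EVID", "MDV", "DV", "WT"]
EVENT_COLUMNS = set(REQUIRED_COLUMNS) | {"BLQ"}


class DatasetError(ValueError):
    """Raised when an event table violates the dataset contract."""


@dataclass(frozen=True)
class SubjectData:
    """Per-subject view used by the likelihood and diagnostics.

    ``obs_times``/``obs_dv`` contain only non-missing observations
    (EVID=0, MDV=0); ``dose_times``/``dose_amounts`` all dose records.
    """

    subject_id: str
    weight: float
    covariates: dict[str, float]
    dose_times: np.ndarray
    dose_amounts: np.ndarray
    obs_times: np.ndarray
    obs_dv: np.ndarray


class Dataset:
    """An ordered event stream for a cohort, validated on construction."""

    def __init__(self, events: pd.DataFrame):
        self._events = _validate(events)

    @property
    def events(self) -> pd.DataFrame:
        return self._events.copy()

    @property
    def subject_ids(self) -> list[str]:
        return list(dict.fromkeys(self._events["ID"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_observations(self) -> int:
        df = self._events
        return int(((df["EVID"] == 0) & (df["MDV"] == 0)).sum())

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self._events.columns if c not in EVENT_COLUMNS]

    def subjects(self) -> Iterator[SubjectData]:
        cov_cols = self.covariate_columns
        for sid, grp in self._events.groupby("ID", sort=False):
            doses = grp[grp["EVID"] == 1]
            obs = grp[(grp["EVID"] == 0) & (grp["MDV"] == 0)]
            covs = {c: float(grp[c].iloc[0]) for c in cov_cols}
            yield SubjectData(
                subject_id=str(sid),
                weight=float(grp["WT"].iloc[0]),
                covariates=covs,
                dose_times=doses["TIME"].to_numpy(dtype=float),
                dose_amounts=doses["AMT"].to_numpy(dtype=float),
                obs_times=obs["TIME"].to_numpy(dtype=float),
                obs_dv=obs["DV"].to_numpy(dtype=float),
            )

    def subset(self, subject_ids: list[str], relabel: bool = True) -> "Dataset":
        """Assemble a new dataset from (possibly repeated) subject ids.

        With ``relabel`` (bootstrap use) each drawn subject gets a fresh
        id ``BS1, BS2, ...`` so that duplicates stay distinct subjects.
        """
        frames = []
        groups = dict(tuple(self._events.groupby("ID", sort=False)))
        for k, sid in enumerate(subject_ids, start=1):
            if sid not in groups:
                raise KeyError(f"unknown subject id {sid!r}")
            grp = groups[sid].copy()
            if relabel:
                grp["ID"] = f"BS{k}"
            frames.append(grp)
        return Dataset(pd.concat(frames, ignore_index=True))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self._events.equals(other._events)

    def __repr__(self) -> str:
        return (
            f"Dataset(n_subjects={self.n_subjects}, "
            f"n_observations={self.n_observations})"
        )


def _validate(events: pd.DataFrame) -> pd.DataFrame:
    df = events.copy().reset_index(drop=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required column(s): {', '.join(missing)}")

    df["ID"] = df["ID"].astype(str)
    for col in ("TIME", "AMT", "DV", "WT"):
        df[col] = pd.to_numeric(
            df[col].replace(".", np.nan), errors="raise"
        ).astype(float)
    for col in ("EVID", "MDV"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    if "BLQ" in df.columns:
        df["BLQ"] = pd.to_numeric(df["BLQ"], errors="raise").astype(int)
    # free covariate columns: normalize to float so a write/read cycle
    # is exactly the identity regardless of CSV integer inference
    for col in df.columns:
        if col not in EVENT_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)

    bad_evid = df[~df["EVID"].isin([0, 1])]
    if len(bad_evid):
        raise DatasetError(f"unknown EVID value at row {bad_evid.index[0] + 1}")

    # "." / missing DV on observation rows maps to MDV=1 (NONMEM convention)
    obs_missing = (df["EVID"] == 0) & df["DV"].isna()
    df.loc[obs_missing, "MDV"] = 1

    for idx, row in df.iterrows():
        if row["TIME"] < 0 or not np.isfinite(row["TIME"]):
            raise DatasetError(f"invalid TIME at row {idx + 1}")
        if row["EVID"] == 1:
            if not row["AMT"] > 0:
                raise DatasetError(f"dose row {idx + 1} must have AMT > 0")
            if not np.isnan(row["DV"]):
                raise DatasetError(f"dose row {idx + 1} must not carry a DV")
        elif not np.isnan(row["DV"]) and row["DV"] < 0:
            raise DatasetError(f"negative DV at row {idx + 1}")

    for sid, grp in df.groupby("ID", sort=False):
        t = grp["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            bad = grp.index[int(np.where(np.diff(t) < 0)[0][0]) + 1]
            raise DatasetError(
                f"TIME decreases within subject {sid!r} at row {bad + 1}"
            )
        w = grp["WT"].to_numpy()
        if np.isnan(w).any() or not np.allclose(w, w[0]):
            raise DatasetError(f"WT must be constant and present for subject {sid!r}")
    return df


def read_dataset(path: str | Path) -> Dataset:
    """Read and validate a NONMEM-layout CSV (``#`` lines are comments)."""
    try:
        df = pd.read_csv(path, comment="#", dtype={"ID": str}, na_values=["."],
                         float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DatasetError(f"cannot parse {path}: {exc}") from exc
    try:
        return Dataset(df)
    except DatasetError as exc:
        raise DatasetError(f"{path}: {exc}") from exc


def write_dataset(
    dataset: Dataset, path: str | Path, header_lines: list[str] | None = None
) -> None:
    """Write a dataset as CSV, '.' for missing DV, optional '#' provenance."""
    df = dataset.events
    df["DV"] = df["DV"].map(lambda v: "." if pd.isna(v) else _fmt(v))
    for col in ("TIME", "AMT", "WT"):
        df[col] = df[col].map(_fmt)
    cov_cols = [c for c in df.columns if c not in EVENT_COLUMNS]
    for col in cov_cols:
        df[col] = df[col].map(_fmt)
    buf = _io.StringIO()
    for line in header_lines or []:
        buf.write(f"# {line}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def _fmt(v: float) -> str:
    """Format numbers compactly but losslessly (round-trip via repr)."""
    if isinstance(v, str):
        return v
    f = float(v)
    return repr(int(f)) if f == int(f) and abs(f) < 1e15 else repr(f)


def summarize(dataset: Dataset) -> dict:
    """Cohort summary: counts, observations per subject, weight, covariates."""
    if dataset.n_subjects == 0:
        raise DatasetError("cannot summarize an empty dataset")
    subs = list(dataset.subjects())
    weights = np.array([s.weight for s in subs])
    n_obs = dataset.n_observations
    summary = {
        "n_subjects": dataset.n_subjects,
        "n_observations": n_obs,
        "obs_per_subject_mean": round(n_obs / dataset.n_subjects, 1),
        "weight_median": float(np.median(weights)),
        "weight_range": (float(weights.min()), float(weights.max())),
        "covariates": {},
    }
    for name in dataset.covariate_columns:
        if name == "BLQ":
            continue
        vals = np.array([s.covariates[name] for s in subs])
        if set(np.unique(vals)) <= {0.0, 1.0}:
            summary["covariates"][name] = {"count": int(vals.sum())}
        else:
            summary["covariates"][name] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "median": float(np.median(vals)),
                "range": (float(vals.min()), float(vals.max())),
            }
    return summary
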