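"""Subject records and the NONMEM-style longitudinal dataset table.

The on-disk format is a plain CSV with the NONMEM column dialect:
ID, TIME (h), EVID (0 observation / 1 dose), AMT (mg, dose rows), SS
(steady-state flag), II (interdose interval, h), DV (concentration, mg/L),
BLQ (1 when the value was below the assay LOD and substituted), plus
time-constant covariate columns (continuous labs and genotype strings).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pk import DoseEvent

__all__ = [
    "Observation",
    "SubjectRecord",
    "REQUIRED_COLUMNS",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "to_subject_records",
    "from_subject_records",
    "genotype_indicator",
]

REQUIRED_COLUMNS = ("ID", "TIME", "EVID", "AMT", "SS", "II", "DV")

#: columns that are structural rather than covariates
_STRUCTURAL = set(REQUIRED_COLUMNS) | {"BLQ"}


@dataclass(frozen=True)
class Observation:
    """One concentration measurement: time after the reference dose (h), mg/L."""

    time: float
    conc: float
    below_lod: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("observation time must be >= 0")
        if not self.conc > 0:
            raise ValueError("observed concentration must be > 0 (sub-LOD values are substituted)")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: dosing events, observations, and time-constant covariates."""

    id: int | str
    doses: tuple[DoseEvent, ...]
    observations: tuple[Observation, ...]
    covariates: dict[str, object] = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return len(self.observations)


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a dataset table; errors name the offending row/column."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    for col in ("TIME", "EVID", "SS", "II"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"non-numeric {col} at row {bad[0]}")
    obs = df["EVID"] == 0
    dose = df["EVID"] == 1
    if not (obs | dose).all():
        row = df.index[~(obs | dose)][0]
        raise ValueError(f"EVID must be 0 or 1 (row {row})")
    bad_dv = df.index[obs & pd.to_numeric(df["DV"], errors="coerce").isna()]
    if len(bad_dv):
        raise ValueError(f"observation row {bad_dv[0]} has a missing or non-numeric DV")
    bad_amt = df.index[dose & ~(pd.to_numeric(df["AMT"], errors="coerce") > 0)]
    if len(bad_amt):
        raise ValueError(f"dose row {bad_amt[0]} needs a positive AMT")
    bad_ii = df.index[(df["SS"] == 1) & ~(pd.to_numeric(df["II"], errors="coerce") > 0)]
    if len(bad_ii):
        raise ValueError(f"steady-state row {bad_ii[0]} needs II > 0")
    cov_cols = [c for c in df.columns if c not in _STRUCTURAL]
    for col in cov_cols:
        per_id = df.groupby("ID")[col].nunique(dropna=False)
        inconsistent = per_id[per_id > 1]
        if len(inconsistent):
            raise ValueError(
                f"covariate {col!r} varies within subject ID={inconsistent.index[0]}"
            )
    return df


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read and validate a NONMEM-style CSV dataset."""
    df = pd.read_csv(path)
    return validate_dataset(df)


def write_dataset(df: pd.DataFrame, path: str | Path) -> None:
    """Validate and write a dataset table to CSV."""
    validate_dataset(df)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def to_subject_records(df: pd.DataFrame) -> list[SubjectRecord]:
    """Convert a validated dataset table into per-subject records."""
    validate_dataset(df)
    cov_cols = [c for c in df.columns if c not in _STRUCTURAL]
    records: list[SubjectRecord] = []
    for sid, grp in df.groupby("ID", sort=False):
        doses = tuple(
            DoseEvent(
                amount=float(r.AMT),
                time=float(r.TIME),
                ss=bool(int(r.SS) == 1),
                tau=float(r.II) if int(r.SS) == 1 else None,
            )
            for r in grp[grp["EVID"] == 1].itertuples()
        )
        obs_rows = grp[grp["EVID"] == 0]
        blq = (
            obs_rows["BLQ"].fillna(0).astype(int)
            if "BLQ" in obs_rows
            else pd.Series(0, index=obs_rows.index)
        )
        observations = tuple(
            Observation(time=float(t), conc=float(dv), below_lod=bool(b))
            for t, dv, b in zip(obs_rows["TIME"], obs_rows["DV"], blq)
        )
        covariates = {c: grp[c].iloc[0] for c in cov_cols}
        records.append(SubjectRecord(id=sid, doses=doses, observations=observations, covariates=covariates))
    return records


def from_subject_records(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Assemble the dataset table from subject records (inverse of to_subject_records)."""
    rows: list[dict] = []
    for rec in records:
        base = {"ID": rec.id, **rec.covariates}
        for d in rec.doses:
            rows.append(
                {**base, "TIME": d.time, "EVID": 1, "AMT": d.amount,
                 "SS": int(d.ss), "II": d.tau if d.ss else 0.0, "DV": np.nan, "BLQ": 0}
            )
        for o in rec.observations:
            rows.append(
                {**base, "TIME": o.time, "EVID": 0, "AMT": np.nan,
                 "SS": 0, "II": 0.0, "DV": o.conc, "BLQ": int(o.below_lod)}
            )
    df = pd.DataFrame(rows)
    cov_cols = [c for c in df.columns if c not in _STRUCTURAL]
    return df[list(REQUIRED_COLUMNS) + ["BLQ"] + cov_cols]


def genotype_indicator(
    value: object, level: str = "GG", *, missing_as: float | None = None
) -> float:
    """0/1 indicator for carrying `level` at a SNP; NaN/None map to `missing_as`."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        if missing_as is None:
            return np.nan
        return float(missing_as)
    return float(str(value) == level)


def covariate_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """One row per subject with its covariates (index = subject id order)."""
    return pd.DataFrame([{"ID": r.id, **r.covariates} for r in records]).set_index("ID")
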