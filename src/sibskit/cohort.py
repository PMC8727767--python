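"""Cohort table: per-patient summaries, the packaged 32-patient fixture, validation.

The canonical in-memory container is a :class:`pandas.DataFrame` wrapped in
:class:`CohortTable`.  One row per patient with the columns

``patient_id, age_bin, age_mid, sex, max_bsr, max_gcs, gose_discharge,
days_discharge, gose_chronic, days_chronic, barbiturates, propofol,
usable_sections, total_sections``

where *max_bsr* is the patient's maximum burst suppression ratio across
usable EEG sections, *max_gcs* the highest Glasgow Coma Scale score over the
ICU stay, and the GOSe columns the Glasgow Outcome Scale extended (1-8) at
hospital discharge and at the chronic (~6 month) follow-up.  Ages are
recorded only as bins; ``age_mid`` is the bin midpoint and is the numeric
"age at injury" covariate everywhere downstream.  Missing values (chronic
assessments that never happened) are encoded as empty cells on disk and as
NaN in memory; they are never imputed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "AGE_BIN_MIDPOINTS",
    "COLUMNS",
    "CohortTable",
    "CohortParseError",
    "CohortValidationError",
    "load_cohort",
    "write_cohort",
    "summarize_cohort",
]

#: Ordered age bins (years) and the midpoints used as the numeric covariate.
AGE_BIN_MIDPOINTS = {
    "18-25": 21.5,
    "25-40": 32.5,
    "40-55": 47.5,
    "55-70": 62.5,
    "70-85": 77.5,
}

#: Column order of the on-disk CSV (age_mid is derived, not stored).
COLUMNS = [
    "patient_id",
    "age_bin",
    "sex",
    "max_bsr",
    "max_gcs",
    "gose_discharge",
    "days_discharge",
    "gose_chronic",
    "days_chronic",
    "barbiturates",
    "propofol",
    "usable_sections",
    "total_sections",
]

_FIXTURE_NAME = "table1_cohort.csv"


class CohortParseError(ValueError):
    """A cohort file could not be parsed (bad header, malformed cell)."""


class CohortValidationError(ValueError):
    """A parsed cohort violates a range or consistency constraint."""


@dataclass
class CohortTable:
    """An ordered collection of patient records plus provenance.

    Attributes
    ----------
    df
        One validated row per patient, columns as in :data:`COLUMNS` plus
        the derived ``age_mid``.
    provenance
        Free text: ``"fixture"`` for the packaged table, ``"synthetic"``
        for simulated cohorts, else the source path.
    """

    df: pd.DataFrame
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        _validate(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def complete_cases(self, timepoint: str) -> pd.DataFrame:
        """Rows with a non-missing outcome at ``timepoint`` ('discharge'|'chronic')."""
        if timepoint == "discharge":
            return self.df
        if timepoint == "chronic":
            return self.df[self.df["gose_chronic"].notna()]
        raise ValueError(f"unknown timepoint {timepoint!r}")


def _validate(df: pd.DataFrame) -> None:
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortParseError(f"cohort table missing columns: {missing_cols}")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise CohortValidationError(f"duplicate patient_id values: {dupes}")

    def _check(mask: pd.Series, col: str, why: str) -> None:
        if mask.any():
            pid = df.loc[mask, "patient_id"].iloc[0]
            raise CohortValidationError(
                f"column {col!r}, patient {pid}: {why}"
            )

    bad_bin = ~df["age_bin"].isin(AGE_BIN_MIDPOINTS)
    _check(bad_bin, "age_bin", f"not one of {sorted(AGE_BIN_MIDPOINTS)}")
    _check(~df["sex"].isin(["M", "F"]), "sex", "must be 'M' or 'F'")
    _check((df["max_bsr"] < 0) | (df["max_bsr"] > 1), "max_bsr", "outside [0, 1]")
    _check((df["max_gcs"] < 3) | (df["max_gcs"] > 15), "max_gcs", "outside [3, 15]")
    _check(
        (df["gose_discharge"] < 1) | (df["gose_discharge"] > 8),
        "gose_discharge", "outside [1, 8]",
    )
    chron = df["gose_chronic"].dropna()
    if ((chron < 1) | (chron > 8)).any():
        raise CohortValidationError("column 'gose_chronic': value outside [1, 8]")
    _check(df["days_discharge"] <= 0, "days_discharge", "must be > 0")
    dchron = df["days_chronic"].dropna()
    if (dchron <= 0).any():
        raise CohortValidationError("column 'days_chronic': value must be > 0")
    _check(
        df["usable_sections"] > df["total_sections"],
        "usable_sections", "exceeds total_sections",
    )
    _check(df["total_sections"] < 1, "total_sections", "must be >= 1")
    # A missing chronic GOSe implies missing days (never vice versa: patients
    # who died before follow-up carry GOSe = 1 with no days-to-assessment).
    _check(
        df["gose_chronic"].isna() & df["days_chronic"].notna(),
        "days_chronic", "present although gose_chronic is missing",
    )


def _fixture_path() -> Path:
    return Path(str(importlib.resources.files("sibskit").joinpath("data", _FIXTURE_NAME)))


def load_cohort(source: Union[str, PathLike, None] = None) -> CohortTable:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    source
        Path to a cohort CSV, or ``None`` / ``"fixture"`` for the packaged
        32-patient table.

    Returns
    -------
    CohortTable
        With ``age_mid`` derived from ``age_bin`` via bin midpoints
        (21.5, 32.5, 47.5, 62.5, 77.5 years).

    Raises
    ------
    CohortParseError
        Empty file, missing header or unparseable cell (the message names
        the offending row and column).
    CohortValidationError
        Any out-of-range or inconsistent value.
    """
    if source is None or source == "fixture":
        path, provenance = _fixture_path(), "fixture"
    else:
        path, provenance = Path(source), str(source)
        if not path.exists():
            raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={"age_bin": str, "sex": str})
    except pd.errors.EmptyDataError as exc:
        raise CohortParseError(f"{path}: empty cohort file") from exc
    if df.empty:
        raise CohortParseError(f"{path}: cohort file has a header but no rows")

    for col, kind in [
        ("patient_id", "Int64"), ("max_gcs", "Int64"),
        ("gose_discharge", "Int64"), ("usable_sections", "Int64"),
        ("total_sections", "Int64"),
    ]:
        try:
            df[col] = df[col].astype(kind)
        except (TypeError, ValueError, KeyError) as exc:
            raise CohortParseError(f"column {col!r}: {exc}") from exc
    for col in ("max_bsr", "gose_chronic", "days_chronic", "days_discharge"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError) as exc:
            raise CohortParseError(f"column {col!r}: {exc}") from exc
    for col in ("barbiturates", "propofol"):
        vals = df[col]
        if vals.dtype != bool:
            mapped = vals.astype(str).str.upper().map({"TRUE": True, "FALSE": False})
            if mapped.isna().any():
                row = int(mapped.index[mapped.isna()][0]) + 2  # 1-based + header
                raise CohortParseError(f"row {row}, column {col!r}: not TRUE/FALSE")
            df[col] = mapped
    df["age_mid"] = df["age_bin"].map(AGE_BIN_MIDPOINTS)
    return CohortTable(df=df, provenance=provenance)


def write_cohort(cohort: CohortTable, path: Union[str, PathLike]) -> None:
    """Write a cohort to CSV in the fixture layout (missing values as empty cells)."""
    out = cohort.df[COLUMNS].copy()
    for col in ("barbiturates", "propofol"):
        out[col] = out[col].map({True: "TRUE", False: "FALSE"})
    out.to_csv(path, index=False)


def summarize_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Descriptive statistics of a cohort.

    Returns a frame indexed by statistic name with columns ``mean``, ``std``
    (sample, n-1 form; NaN when n = 1) and ``n``, covering days to each GOSe
    assessment, usable EEG sections, percent of sections used, and counts of
    female sex and sedative exposure.
    """
    if len(cohort) == 0:
        raise CohortValidationError("empty cohort")
    df = cohort.df
    pct_used = 100.0 * df["usable_sections"] / df["total_sections"]

    def _row(series: pd.Series) -> dict:
        s = series.dropna()
        return {
            "mean": float(s.mean()),
            "std": float(s.std(ddof=1)) if len(s) > 1 else float("nan"),
            "n": int(len(s)),
        }

    rows = {
        "days_discharge": _row(df["days_discharge"]),
        "days_chronic": _row(df["days_chronic"]),
        "usable_sections": _row(df["usable_sections"]),
        "percent_sections_used": _row(pct_used),
        "n_female": {"mean": float((df["sex"] == "F").sum()), "std": np.nan, "n": len(df)},
        "n_male": {"mean": float((df["sex"] == "M").sum()), "std": np.nan, "n": len(df)},
        "n_barbiturates": {"mean": float(df["barbiturates"].sum()), "std": np.nan, "n": len(df)},
        "n_propofol": {"mean": float(df["propofol"].sum()), "std": np.nan, "n": len(df)},
    }
    return pd.DataFrame(rows).T[["mean", "std", "n"]]
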