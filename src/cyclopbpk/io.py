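"""Table schemas, atomic file output and the run manifest.

Delimited-text dialect: comma-separated, UTF-8, decimal point, mandatory
header row.  All writes are atomic (write to a temp file in the target
directory, then rename), so interrupted runs never leave truncated tables.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import os
import tempfile
from pathlib import Path

import pandas as pd

from .physiology import Demographics, impute_height

__all__ = [
    "read_patients",
    "read_observations",
    "read_tdm_tables",
    "bundled_patients_path",
    "atomic_write_text",
    "write_frame",
    "write_manifest",
    "SchemaError",
]

log = logging.getLogger("cyclopbpk")

PATIENT_COLUMNS = ("patient_id", "sex", "age_years", "body_weight_kg")
OBSERVATION_COLUMNS = ("patient_id", "dose_mg", "c0_obs")

_SEX_ALIASES = {"m": "male", "male": "male", "f": "female", "female": "female"}


class SchemaError(ValueError):
    """A table failed validation; the message names the offending row/column."""


def bundled_patients_path() -> Path:
    """Bundled biometrics of the 32-patient renal-transplant cohort."""
    return Path(importlib.resources.files("cyclopbpk").joinpath(
        "data/renal_cohort_patients.csv"))


def _read_csv(path, required: tuple, label: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{label} file not found: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{label} file {path} contains no rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} file {path} lacks required columns {missing}")
    extra = [c for c in df.columns if c not in required and c != "body_height_cm"]
    if extra:
        log.warning("%s file %s: ignoring unknown columns %s", label, path, extra)
    return df


def read_patients(path) -> pd.DataFrame:
    """Read and validate a patient biometrics table.

    Columns: patient_id, sex, age_years, body_weight_kg, optional
    body_height_cm (blank heights are imputed from the sex/age average and
    flagged in the log).
    """
    df = _read_csv(path, PATIENT_COLUMNS, "patients")
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise SchemaError(f"duplicate patient_id {dup!r}")
    df["sex"] = df["sex"].astype(str).str.strip().str.lower().map(_SEX_ALIASES)
    if df["sex"].isna().any():
        row = int(df.index[df["sex"].isna()][0])
        raise SchemaError(f"patients row {row}: sex must be male/female (m/f)")
    for col in ("age_years", "body_weight_kg"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any() or (df[col] <= 0).any():
            row = int(df.index[~(df[col] > 0)][0])
            raise SchemaError(f"patients row {row}: non-numeric or non-positive {col}")
    if "body_height_cm" not in df.columns:
        df["body_height_cm"] = pd.NA
    df["body_height_cm"] = pd.to_numeric(df["body_height_cm"], errors="coerce")
    blank = df["body_height_cm"].isna()
    if blank.any():
        log.info("imputing body height for %d patient(s): %s",
                 int(blank.sum()), ", ".join(df.loc[blank, "patient_id"]))
        df.loc[blank, "body_height_cm"] = [
            impute_height(s, a) for s, a in zip(df.loc[blank, "sex"], df.loc[blank, "age_years"])
        ]
    return df[list(PATIENT_COLUMNS) + ["body_height_cm"]]


def read_observations(path) -> pd.DataFrame:
    """Read and validate trough observations (patient_id, dose_mg, c0_obs ng/ml)."""
    df = _read_csv(path, OBSERVATION_COLUMNS, "observations")
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    for col in ("dose_mg", "c0_obs"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any() or (df[col] <= 0).any():
            row = int(df.index[~(df[col] > 0)][0])
            raise SchemaError(f"observations row {row}: non-numeric or non-positive {col}")
    return df[list(OBSERVATION_COLUMNS)]


def read_tdm_tables(patients_path, observations_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validated (patients, observations) pair for the comparison pipeline."""
    patients = read_patients(patients_path)
    observations = read_observations(observations_path)
    unknown = set(observations["patient_id"]) - set(patients["patient_id"])
    if unknown:
        raise SchemaError(f"observations reference unknown patient ids {sorted(unknown)}")
    return patients, observations


def demographics_from_row(row) -> Demographics:
    return Demographics(sex=row["sex"], age_years=float(row["age_years"]),
                        body_weight_kg=float(row["body_weight_kg"]),
                        body_height_cm=float(row["body_height_cm"]))


def atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_frame(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    atomic_write_text(path, df.to_csv(index=False, float_format=float_format))


def write_manifest(path, **entries) -> None:
    """JSON manifest capturing every parameter of a run (full provenance)."""
    atomic_write_text(path, json.dumps(entries, indent=2, sort_keys=True, default=str) + "\n")
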