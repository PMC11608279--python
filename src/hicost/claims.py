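"""Claims tables: schema, validation, I/O and currency handling.

Two tabular containers carry everything downstream (both plain
:class:`pandas.DataFrame`):

* the **patient table** — one row per insured patient:
  ``patient_id, age, gender, poverty``;
* the **encounter table** — one row per outpatient visit or admission:
  ``encounter_id, patient_id, encounter_type, year, principal_dx,
  department, in_county, los_days, total_spend, oop_spend``.

All spending is stored in CNY; conversion to USD happens only at report
time (2019 exchange rate CNY 6.90 per US$ 1.00 by default).

Rows violating the documented invariants (out-of-pocket exceeding total,
negative spending, unparseable diagnosis codes, ...) are not silently
dropped: :func:`read_claims` collects them into a reject frame with a
reason per row and loads the rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .codes import CodeValidationError, normalize_icd10

__all__ = [
    "PATIENT_COLUMNS",
    "ENCOUNTER_COLUMNS",
    "DEPARTMENTS",
    "CNY_PER_USD",
    "cny_to_usd",
    "validate_encounters",
    "validate_patients",
    "read_claims",
    "write_claims",
]

log = logging.getLogger(__name__)

PATIENT_COLUMNS = ["patient_id", "age", "gender", "poverty"]
ENCOUNTER_COLUMNS = [
    "encounter_id",
    "patient_id",
    "encounter_type",
    "year",
    "principal_dx",
    "department",
    "in_county",
    "los_days",
    "total_spend",
    "oop_spend",
]

#: Hospital departments recorded for admissions.
DEPARTMENTS = [
    "internal medicine",
    "surgery",
    "orthopedics",
    "gynecology",
    "obstetrics",
    "pediatrics",
    "oncology",
    "ophthalmology, ENT, stomatology",
    "rehabilitation",
]

CNY_PER_USD = 6.90


def cny_to_usd(amount_cny, rate: float = CNY_PER_USD):
    """Convert CNY to USD at the (configurable) 2019 exchange rate.

    Accepts scalars or array-likes; negative amounts are rejected.
    """
    arr = np.asarray(amount_cny, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative CNY amount")
    out = arr / rate
    return float(out) if np.isscalar(amount_cny) else out


def _normalize_dx_column(dx: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Normalize a diagnosis column; returns (normalized, bad-mask)."""
    uniq = dx.dropna().unique()
    lut, bad_codes = {}, set()
    for code in uniq:
        try:
            lut[code] = normalize_icd10(code)
        except CodeValidationError:
            bad_codes.add(code)
    normalized = dx.map(lut)
    bad = dx.isin(bad_codes) | dx.isna()
    return normalized, bad


def validate_patients(patients: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a patient table into (valid, rejected-with-reason)."""
    missing = set(PATIENT_COLUMNS) - set(patients.columns)
    if missing:
        raise ValueError(f"patient table missing required columns: {sorted(missing)}")
    reasons = pd.Series("", index=patients.index, dtype=object)
    bad_age = ~patients["age"].between(0, 120)
    reasons[bad_age] += "age outside [0,120];"
    bad_gender = ~patients["gender"].isin(["male", "female"])
    reasons[bad_gender] += "gender not in {male,female};"
    mask = reasons != ""
    rejects = patients[mask].assign(reject_reason=reasons[mask])
    return patients[~mask].copy(), rejects


def validate_encounters(encounters: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an encounter table into (valid, rejected-with-reason).

    Normalizes ``principal_dx`` in place on the valid rows.
    """
    missing = set(ENCOUNTER_COLUMNS) - set(encounters.columns)
    if missing:
        raise ValueError(f"encounter table missing required columns: {sorted(missing)}")
    enc = encounters.copy()
    reasons = pd.Series("", index=enc.index, dtype=object)

    bad_type = ~enc["encounter_type"].isin(["outpatient", "inpatient"])
    reasons[bad_type] += "unknown encounter_type;"
    neg = (enc["total_spend"] < 0) | (enc["oop_spend"] < 0)
    reasons[neg] += "negative spending;"
    oop_gt = enc["oop_spend"] > enc["total_spend"] + 1e-9
    reasons[oop_gt] += "oop_spend exceeds total_spend;"
    out_los = (enc["encounter_type"] == "outpatient") & (enc["los_days"].fillna(0) != 0)
    reasons[out_los] += "outpatient encounter with nonzero los_days;"
    normalized, bad_dx = _normalize_dx_column(enc["principal_dx"])
    reasons[bad_dx] += "unparseable principal_dx;"
    enc.loc[~bad_dx, "principal_dx"] = normalized[~bad_dx]

    mask = reasons != ""
    rejects = enc[mask].assign(reject_reason=reasons[mask])
    valid = enc[~mask].copy()
    if mask.any():
        log.warning("rejected %d of %d encounter rows", int(mask.sum()), len(enc))
    return valid, rejects


@dataclass
class ClaimsBundle:
    """Loaded claims with validation rejects kept for inspection."""

    patients: pd.DataFrame
    encounters: pd.DataFrame
    patient_rejects: pd.DataFrame
    encounter_rejects: pd.DataFrame


def read_claims(path: str | Path, reject_path: str | Path | None = None) -> ClaimsBundle:
    """Read ``patients.csv`` and ``encounters.csv`` from a claims directory.

    Invalid rows are collected (optionally written next to the inputs or to
    ``reject_path``) and excluded from the returned tables.  A missing
    required column fails fast naming the column; a zero-row encounter file
    loads as an empty table with a warning.
    """
    path = Path(path)
    patients = pd.read_csv(path / "patients.csv", dtype={"patient_id": str})
    encounters = pd.read_csv(
        path / "encounters.csv", dtype={"patient_id": str, "principal_dx": str}
    )
    if len(encounters) == 0:
        log.warning("encounter file %s has zero rows", path / "encounters.csv")
    patients, prej = validate_patients(patients)
    encounters, erej = validate_encounters(encounters)
    log.info(
        "loaded %d patients (%d rejected), %d encounters (%d rejected)",
        len(patients), len(prej), len(encounters), len(erej),
    )
    if reject_path is not None and (len(prej) or len(erej)):
        reject_path = Path(reject_path)
        reject_path.mkdir(parents=True, exist_ok=True)
        if len(prej):
            prej.to_csv(reject_path / "patient_rejects.csv", index=False)
        if len(erej):
            erej.to_csv(reject_path / "encounter_rejects.csv", index=False)
    return ClaimsBundle(patients, encounters, prej, erej)


def write_claims(
    patients: pd.DataFrame,
    encounters: pd.DataFrame,
    path: str | Path,
    latent_groups: pd.DataFrame | None = None,
) -> Path:
    """Write claims tables as CSV; ground-truth labels go to a sidecar.

    The latent-group sidecar is written separately (``latent_groups.csv``)
    so the analysis pipeline cannot accidentally consume it as a feature.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    patients.to_csv(path / "patients.csv", index=False)
    encounters.to_csv(path / "encounters.csv", index=False)
    if latent_groups is not None:
        latent_groups.to_csv(path / "latent_groups.csv", index=False)
    return path
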