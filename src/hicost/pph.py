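"""Potentially preventable hospitalizations and preventable inpatient cost.

An admission is *potentially preventable* (a PPH) when its principal
ICD-10 diagnosis falls into an ambulatory-care-sensitive condition list
— heart failure, diabetes, hypertension, asthma and the like, for which
good outpatient care can usually avert hospitalization.  Flagging is a
longest-prefix match on the normalized principal diagnosis only;
outpatient encounters are never flagged.  No complication/comorbidity
exclusions are applied by default (an exclusion-list hook exists but
ships empty).

A patient's **preventable inpatient cost (PIC)** is the total spending —
reimbursed plus out-of-pocket — of their flagged admissions.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .claims import cny_to_usd
from .codes import CodeMap

__all__ = ["flag_pph", "compute_pic", "share", "subgroup_report"]


def flag_pph(
    encounters: pd.DataFrame,
    pqi_map: CodeMap,
    exclusions: CodeMap | None = None,
) -> pd.DataFrame:
    """Flag admissions whose principal diagnosis is ambulatory-care sensitive.

    Returns one row per encounter: ``encounter_id, patient_id, pph,
    matched_category, matched_prefix``.  ``exclusions`` (a code map of
    disqualifying principal diagnoses) is an optional hook and empty by
    default.
    """
    enc = encounters
    is_adm = (enc["encounter_type"] == "inpatient").to_numpy()
    dx = enc["principal_dx"]

    uniq = dx[is_adm].unique()
    cat_lut, pref_lut = {}, {}
    for code in uniq:
        cat_lut[code] = pqi_map.classify(code)
        pref_lut[code] = next(
            (p for p in sorted(pqi_map.entries, key=len, reverse=True)
             if code.startswith(p)),
            None,
        )
    category = dx.map(cat_lut).where(is_adm)
    prefix = dx.map(pref_lut).where(is_adm)
    pph = category.notna() & is_adm
    if exclusions is not None and exclusions.entries:
        excluded = exclusions.classify_many(dx).notna()
        pph &= ~excluded
        category = category.where(pph)
        prefix = prefix.where(pph)
    return pd.DataFrame(
        {
            "encounter_id": enc["encounter_id"],
            "patient_id": enc["patient_id"],
            "pph": pph.to_numpy(),
            "matched_category": category.to_numpy(),
            "matched_prefix": prefix.to_numpy(),
        }
    )


def compute_pic(flags: pd.DataFrame, encounters: pd.DataFrame) -> pd.Series:
    """Per-patient preventable inpatient cost (CNY).

    Sum of ``total_spend`` over each patient's flagged admissions; 0 for
    patients with none.  Conservation: the series total equals the total
    spending of all flagged admissions.
    """
    flagged_ids = flags.loc[flags["pph"], "encounter_id"]
    flagged = encounters[encounters["encounter_id"].isin(flagged_ids)]
    pic = flagged.groupby("patient_id")["total_spend"].sum()
    pic = pic.reindex(encounters["patient_id"].unique(), fill_value=0.0)
    pic.name = "pic"
    return pic


def share(numerator: float, denominator: float, decimals: int = 2) -> float | None:
    """Percentage ``100*num/den`` rounded half-up; None for a zero denominator.

    Half-up (not banker's) rounding matches how claims reports print
    percentages, e.g. 12 095 / 32 108 -> 37.67.
    """
    if denominator == 0:
        return None
    pct = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def subgroup_report(
    subgroup_labels: pd.Series,
    summaries: pd.DataFrame,
    pic: pd.Series,
    decimals: int = 2,
) -> pd.DataFrame:
    """Utilization and spending profile per subgroup (USD at report time).

    One row per subgroup: patient count, admissions / LOS / visit means
    with SDs, mean total spending in USD, and the percentage of total
    spending that is preventable (PIC), inpatient, and out-of-pocket.
    Empty subgroups yield a row with n=0 and blank statistics.
    """
    df = summaries.set_index("patient_id").join(pic.rename("pic"), how="left")
    df["pic"] = df["pic"].fillna(0.0)
    df = df.loc[subgroup_labels.index]
    df["subgroup"] = subgroup_labels

    rows = []
    for sg, d in df.groupby("subgroup", sort=True):
        n = len(d)
        if n == 0:
            rows.append({"subgroup": sg, "n_patients": 0})
            continue
        total = d["total_spend"].sum()
        rows.append(
            {
                "subgroup": sg,
                "n_patients": n,
                "admissions_mean": d["admissions"].mean(),
                "admissions_sd": d["admissions"].std(ddof=1),
                "avg_los_mean": d["avg_los"].mean(),
                "avg_los_sd": d["avg_los"].std(ddof=1),
                "outpatient_visits_mean": d["outpatient_visits"].mean(),
                "outpatient_visits_sd": d["outpatient_visits"].std(ddof=1),
                "total_spend_mean_usd": cny_to_usd(d["total_spend"].mean()),
                "pic_pct_of_total": share(d["pic"].sum(), total, decimals),
                "inpatient_pct_of_total": share(d["inpatient_spend"].sum(), total, decimals),
                "oop_pct_of_total": share(d["oop_spend"].sum(), total, decimals),
            }
        )
    return pd.DataFrame(rows)
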