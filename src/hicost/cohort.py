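"""Patient-year aggregation and high-cost cohort selection.

High-cost patients are defined as the top 10% of patients by annual total
individual spending (inpatient plus outpatient).  Selection takes exactly
``floor(fraction * N)`` patients after a stable sort by (spending
descending, patient_id ascending); the tie-break is documented here and
isolated in :func:`select_high_cost` so runs are reproducible even when
spending ties straddle the cutoff.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["summarize_patient_year", "select_high_cost", "cohort_table"]


def summarize_patient_year(
    encounters: pd.DataFrame, patients: pd.DataFrame, year: int
) -> pd.DataFrame:
    """Aggregate encounters of one index year to per-patient summaries.

    One row per patient with at least one encounter in ``year``; spending
    and utilization totals equal the column sums of that patient's
    encounters.  ``avg_los`` is total inpatient days over admissions (0
    for patients without admissions).
    """
    enc = encounters[encounters["year"] == year]
    if len(enc) == 0:
        return pd.DataFrame(
            columns=[
                "patient_id", "total_spend", "inpatient_spend", "oop_spend",
                "admissions", "admissions_in_county", "admissions_out_county",
                "total_los_days", "avg_los", "outpatient_visits",
                "visits_in_county", "visits_out_county", "high_cost",
            ]
        )
    is_adm = enc["encounter_type"] == "inpatient"
    g = enc.assign(
        inpatient_spend=enc["total_spend"].where(is_adm, 0.0),
        admissions=is_adm.astype(int),
        admissions_in_county=(is_adm & enc["in_county"]).astype(int),
        admissions_out_county=(is_adm & ~enc["in_county"]).astype(int),
        total_los_days=enc["los_days"].where(is_adm, 0),
        outpatient_visits=(~is_adm).astype(int),
        visits_in_county=(~is_adm & enc["in_county"]).astype(int),
        visits_out_county=(~is_adm & ~enc["in_county"]).astype(int),
    ).groupby("patient_id", sort=True).agg(
        total_spend=("total_spend", "sum"),
        inpatient_spend=("inpatient_spend", "sum"),
        oop_spend=("oop_spend", "sum"),
        admissions=("admissions", "sum"),
        admissions_in_county=("admissions_in_county", "sum"),
        admissions_out_county=("admissions_out_county", "sum"),
        total_los_days=("total_los_days", "sum"),
        outpatient_visits=("outpatient_visits", "sum"),
        visits_in_county=("visits_in_county", "sum"),
        visits_out_county=("visits_out_county", "sum"),
    )
    g["avg_los"] = np.where(
        g["admissions"] > 0, g["total_los_days"] / g["admissions"].replace(0, 1), 0.0
    )
    g["high_cost"] = False
    return g.reset_index()


def select_high_cost(summaries: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Flag the top ``fraction`` of patients by total spending.

    Exactly ``floor(fraction * N)`` patients are flagged; every flagged
    patient spends at least as much as every unflagged one.  Ties at the
    cutoff are broken by patient_id (ascending) under a stable sort.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0,1)")
    n = len(summaries)
    k = math.floor(fraction * n)
    if k < 1:
        raise ValueError(
            f"cannot form a nonempty top-{fraction:.0%} group from {n} patients"
        )
    out = summaries.sort_values(
        ["total_spend", "patient_id"], ascending=[False, True], kind="stable"
    ).copy()
    out["high_cost"] = False
    out.iloc[: k, out.columns.get_loc("high_cost")] = True
    return out.sort_values("patient_id", kind="stable").reset_index(drop=True)


def _mean_sd(s: pd.Series) -> str:
    return f"{s.mean():.2f} ({s.std(ddof=1):.2f})"


def _n_pct(k: int, n: int) -> str:
    return f"{k} ({100 * k / n:.2f})" if n else ""


def cohort_table(
    summaries: pd.DataFrame,
    patients: pd.DataFrame,
    chronic_flags: pd.DataFrame | None = None,
    adrg_flags: pd.DataFrame | None = None,
    top_n: int = 10,
) -> pd.DataFrame:
    """Cohort description: overall vs high-cost vs non-high-cost columns.

    Emits mean (SD) rows for age, utilization and spending, N (%) rows for
    gender, poverty and admission-count bands, and — when binary flag
    frames indexed by patient_id are supplied — the ``top_n`` most
    prevalent chronic conditions and diagnosis groups ranked among
    high-cost patients.
    """
    df = summaries.merge(patients, on="patient_id", how="left")
    strata = {
        "overall": df,
        "high_cost": df[df["high_cost"]],
        "non_high_cost": df[~df["high_cost"]],
    }
    rows: list[dict] = []

    def add(label: str, fn) -> None:
        rows.append({"row": label, **{s: fn(d) for s, d in strata.items()}})

    add("N", lambda d: str(len(d)))
    add("Age (mean, SD)", lambda d: _mean_sd(d["age"]))
    add("Male, No. (%)", lambda d: _n_pct(int((d["gender"] == "male").sum()), len(d)))
    add("Poverty-stricken, No. (%)", lambda d: _n_pct(int(d["poverty"].sum()), len(d)))
    add("Admissions (mean, SD)", lambda d: _mean_sd(d["admissions"]))
    add("Admissions within county (mean, SD)", lambda d: _mean_sd(d["admissions_in_county"]))
    add("Admissions outside county (mean, SD)", lambda d: _mean_sd(d["admissions_out_county"]))
    for band, sel in [
        ("0", lambda a: a == 0), ("1", lambda a: a == 1),
        ("2", lambda a: a == 2), (">=3", lambda a: a >= 3),
    ]:
        add(
            f"Admissions {band}, No. (%)",
            lambda d, sel=sel: _n_pct(int(sel(d["admissions"]).sum()), len(d)),
        )
    add("Average LOS (mean, SD)", lambda d: _mean_sd(d["avg_los"]))
    add("Outpatient visits (mean, SD)", lambda d: _mean_sd(d["outpatient_visits"]))
    add("Total spending (mean, SD), CNY", lambda d: _mean_sd(d["total_spend"]))
    add("Out-of-pocket spending (mean, SD), CNY", lambda d: _mean_sd(d["oop_spend"]))

    for label, flags in [("chronic condition", chronic_flags), ("diagnosis group", adrg_flags)]:
        if flags is None:
            continue
        merged = df.set_index("patient_id").join(flags, how="left").fillna(0)
        hc = merged[merged["high_cost"]]
        prevalence = hc[flags.columns].sum().sort_values(ascending=False)
        for name in prevalence.index[:top_n]:
            rows.append(
                {
                    "row": f"Top {label}: {name}, No. (%)",
                    **{
                        s: _n_pct(int(d.set_index("patient_id").join(flags, how="left")
                                      .fillna(0)[name].sum()), len(d))
                        for s, d in strata.items()
                    },
                }
            )
    return pd.DataFrame(rows)
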