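"""Binary clustering features for the high-cost cohort.

Each high-cost patient becomes one row of 0/1 variables from four
sources:

* ``demographic`` — gender plus one-hot age bins (0-14, 15-44, 45-64,
  65+ by default; clustering inputs are binary, so age is binned);
* ``ADRG`` — diagnosis-group flags: any index-year encounter whose
  principal diagnosis classifies into the group;
* ``comorbidity`` — chronic-condition flags with a multi-year lookback
  (any encounter in the full claims window classifying under the
  chronic-condition map);
* ``department`` — hospitalized in that department in the index year.

Low-variance variables are removed before clustering: diagnosis-group
columns with prevalence below 1% and comorbidity columns below 0.1%
(strict thresholds, measured on the high-cost cohort before
deduplication).  Identical rows are then collapsed, keeping a
representative map so cluster labels can be propagated back to every
patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .claims import DEPARTMENTS
from .codes import CodeMap

__all__ = [
    "FeatureMatrix",
    "DedupResult",
    "DEFAULT_AGE_BINS",
    "build_features",
    "filter_low_prevalence",
    "deduplicate",
]

DEFAULT_AGE_BINS = ((0, 14), (15, 44), (45, 64), (65, 200))

ADRG_MIN_PREVALENCE = 0.01
COMORBIDITY_MIN_PREVALENCE = 0.001


@dataclass
class FeatureMatrix:
    """Patients x binary variables, with per-column provenance.

    ``matrix`` is indexed by patient_id with int8 0/1 entries; ``sources``
    maps each column to its origin (demographic / ADRG / comorbidity /
    department); ``prevalence`` records the column means at build time.
    """

    matrix: pd.DataFrame
    sources: dict[str, str]
    prevalence: pd.Series

    def __post_init__(self) -> None:
        if list(self.matrix.columns) != list(self.sources):
            raise ValueError("sources must cover exactly the matrix columns")
        vals = self.matrix.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("feature matrix entries must be 0/1")

    def columns_of(self, source: str) -> list[str]:
        return [c for c, s in self.sources.items() if s == source]


@dataclass
class DedupResult:
    """Unique feature rows plus the patient -> unique-row mapping."""

    unique: pd.DataFrame          # indexed by unique_row_id
    representative: pd.Series     # patient_id -> unique_row_id
    multiplicity: pd.Series       # unique_row_id -> count

    def expand(self) -> pd.DataFrame:
        """Reconstruct the original row multiset (per patient)."""
        return self.unique.loc[self.representative].set_axis(self.representative.index)


def _any_flag(
    encounters: pd.DataFrame,
    code_map: CodeMap,
    patient_ids: pd.Index,
    categories: list[str],
) -> pd.DataFrame:
    """Patient x category incidence from classified principal diagnoses."""
    cats = code_map.classify_many(encounters["principal_dx"])
    hit = encounters.loc[cats.notna(), ["patient_id"]].assign(category=cats.dropna())
    flags = (
        pd.crosstab(hit["patient_id"], hit["category"]).clip(upper=1)
        .reindex(index=patient_ids, columns=categories, fill_value=0)
        .astype(np.int8)
    )
    return flags


def build_features(
    high_cost_summaries: pd.DataFrame,
    encounters_index: pd.DataFrame,
    encounters_all: pd.DataFrame,
    patients: pd.DataFrame,
    adrg_map: CodeMap,
    comorbidity_map: CodeMap,
    age_bins: tuple[tuple[int, int], ...] = DEFAULT_AGE_BINS,
) -> FeatureMatrix:
    """Build the binary clustering matrix for the flagged cohort.

    ``encounters_index`` are index-year encounters (drive ADRG and
    department flags); ``encounters_all`` span the full lookback window
    (drive comorbidity flags, so a chronic diagnosis seen only in an
    earlier year still sets its flag).
    """
    cohort = high_cost_summaries[high_cost_summaries["high_cost"]]
    ids = pd.Index(sorted(cohort["patient_id"]), name="patient_id")
    if len(ids) == 0:
        raise ValueError("no high-cost patients flagged; run select_high_cost first")

    demo = patients.set_index("patient_id").reindex(ids)
    blocks: list[pd.DataFrame] = []
    sources: dict[str, str] = {}

    demo_block = pd.DataFrame(index=ids)
    demo_block["female"] = (demo["gender"] == "female").astype(np.int8)
    for lo, hi in age_bins:
        label = f"age_{lo}_{hi}" if hi < 200 else f"age_{lo}_plus"
        demo_block[label] = demo["age"].between(lo, hi).astype(np.int8)
    blocks.append(demo_block)
    sources.update({c: "demographic" for c in demo_block.columns})

    e_idx = encounters_index[encounters_index["patient_id"].isin(ids)]
    e_all = encounters_all[encounters_all["patient_id"].isin(ids)]

    adrg = _any_flag(e_idx, adrg_map, ids, adrg_map.categories)
    adrg.columns = [f"adrg: {c}" for c in adrg.columns]
    blocks.append(adrg)
    sources.update({c: "ADRG" for c in adrg.columns})

    como = _any_flag(e_all, comorbidity_map, ids, comorbidity_map.categories)
    como.columns = [f"comorbidity: {c}" for c in como.columns]
    blocks.append(como)
    sources.update({c: "comorbidity" for c in como.columns})

    inp = e_idx[e_idx["encounter_type"] == "inpatient"]
    dept = (
        pd.crosstab(inp["patient_id"], inp["department"]).clip(upper=1)
        .reindex(index=ids, columns=DEPARTMENTS, fill_value=0)
        .astype(np.int8)
    )
    dept.columns = [f"department: {c}" for c in dept.columns]
    blocks.append(dept)
    sources.update({c: "department" for c in dept.columns})

    matrix = pd.concat(blocks, axis=1)
    return FeatureMatrix(matrix=matrix, sources=sources, prevalence=matrix.mean())


def filter_low_prevalence(
    fm: FeatureMatrix,
    adrg_min: float = ADRG_MIN_PREVALENCE,
    comorbidity_min: float = COMORBIDITY_MIN_PREVALENCE,
) -> FeatureMatrix:
    """Drop rare diagnosis-group and comorbidity columns (strict '<').

    Demographic and department columns are never dropped.  Idempotent:
    re-filtering a filtered matrix changes nothing.
    """
    prevalence = fm.matrix.mean()
    keep = []
    for col in fm.matrix.columns:
        src, p = fm.sources[col], prevalence[col]
        if src == "ADRG" and p < adrg_min:
            continue
        if src == "comorbidity" and p < comorbidity_min:
            continue
        keep.append(col)
    if not keep:
        raise ValueError(
            "prevalence filtering removed every column; review thresholds"
        )
    return FeatureMatrix(
        matrix=fm.matrix[keep],
        sources={c: fm.sources[c] for c in keep},
        prevalence=fm.prevalence[keep],
    )


def deduplicate(fm: FeatureMatrix) -> DedupResult:
    """Collapse identical feature rows.

    Returns the unique rows (indexed ``u0, u1, ...`` in order of first
    appearance), a patient -> unique-row map, and per-row multiplicities;
    expanding unique rows through the map reproduces the original row
    multiset exactly.
    """
    m = fm.matrix
    grouped = m.groupby(list(m.columns), sort=False)
    rep = pd.Series(grouped.ngroup().to_numpy(), index=m.index, name="unique_row_id")
    rep = rep.map(lambda i: f"u{i}")
    first = ~rep.duplicated()
    unique = m[first].set_axis(rep[first]).sort_index(key=lambda ix: ix.str[1:].astype(int))
    unique.index.name = "unique_row_id"
    multiplicity = rep.value_counts().reindex(unique.index)
    multiplicity.name = "multiplicity"
    return DedupResult(unique=unique, representative=rep, multiplicity=multiplicity)
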