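"""Synthetic rural-claims population generator.

The analysis pipeline was designed for county-level insurance claims
(one row per outpatient visit or admission, with an ICD-10 principal
diagnosis and a total / out-of-pocket spending split).  Such extracts are
not publicly depositable, so this module generates populations with the
statistical structure the analysis assumes:

* a heavy right tail of annual spending — by default the top decile of
  patients holds roughly three quarters of all spending, driven by a
  lognormal patient-severity multiplier and overdispersed
  (negative-binomial) admission counts;
* repeat admissions concentrated in a set of **planted latent subgroups**
  (chronic disease, surgery-needing non-trauma disease, female disease,
  cancer, ...), each with its own diagnosis pool, chronic-condition
  profile, department mix, admission-count and length-of-stay
  distributions;
* chronic conditions that persist across the simulated years, surfacing
  as prior-year outpatient visits (so a comorbidity lookback over
  2017-2019 has something to find);
* a configurable fraction of each group's admissions carrying an
  ambulatory-care-sensitive principal diagnosis, giving the preventable-
  hospitalization flagger a known ground truth.

Ground-truth group labels are returned (and written) as a separate
sidecar table so the pipeline cannot accidentally consume them.
Everything is driven by a single integer seed: identical configs produce
byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .claims import DEPARTMENTS
from .codes import CodeMap, load_packaged_map, normalize_icd10

__all__ = [
    "LatentGroupSpec",
    "SimConfig",
    "DEFAULT_GROUPS",
    "recovery_benchmark_groups",
    "generate_population",
    "plant_pph_admissions",
]

_INDEX_YEAR = 2019

#: Per-department base admission cost (CNY); tuned so inpatient care
#: dominates high-cost spending and surgical/oncology stays are dearest.
_DEPT_BASE_CNY = {
    "internal medicine": 2500.0,
    "surgery": 4200.0,
    "orthopedics": 5000.0,
    "gynecology": 3200.0,
    "obstetrics": 3000.0,
    "pediatrics": 2000.0,
    "oncology": 5500.0,
    "ophthalmology, ENT, stomatology": 4000.0,
    "rehabilitation": 2200.0,
}

# Principal-diagnosis pools for unstructured (background) patients.
_BG_VISIT_DX = {
    "J06900": 0.28, "R42X00": 0.13, "K29700": 0.11, "R10400": 0.10,
    "M54502": 0.08, "I10002": 0.08, "J18000": 0.07, "I25103": 0.05,
    "I63900": 0.04, "E11901": 0.03, "M51202": 0.03,
}
_BG_ADMIT_DX = {
    "J18000": 0.13, "I25103": 0.10, "I63900": 0.10, "I10002": 0.09,
    "K29700": 0.08, "K56000": 0.08, "M51202": 0.08, "J06900": 0.06,
    "R42X00": 0.06, "S72001": 0.05, "K80501": 0.05, "N20001": 0.05,
    "I50900": 0.05, "C34900": 0.02,
}
# Background chronic-condition prevalences (category -> probability),
# shaped like the leading chronic conditions of a rural claims population.
_BG_CHRONIC = {
    "chronic pulmonary disease": 0.20,
    "hypertension, uncomplicated": 0.14,
    "diabetes, uncomplicated": 0.06,
    "peptic ulcer disease excluding bleeding": 0.01,
}


@dataclass(frozen=True)
class LatentGroupSpec:
    """One planted clinical subgroup of the high-cost tail.

    ``share`` is the fraction of the *whole simulated population* that
    belongs to the group; members are driven into the top spending decile
    by their admission counts and per-stay costs.  ``pph_fraction`` is the
    probability that an admission carries an ambulatory-care-sensitive
    (preventable-hospitalization-eligible) principal diagnosis.
    """

    name: str
    share: float
    diagnosis_pool: dict[str, float]
    department_pool: dict[str, float]
    chronic_pool: tuple[str, ...] = ()
    admissions_mean: float = 2.0
    admissions_dispersion: float = 2.0
    los_meanlog: float = math.log(9.0)
    los_sigma: float = 0.45
    pph_fraction: float = 0.0
    age_range: tuple[int, int] = (15, 90)
    female_share: float = 0.5
    chronic_prob: float = 0.8
    spend_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.share < 1:
            raise ValueError(f"group {self.name!r}: share must be in (0,1)")
        if not 0 <= self.pph_fraction <= 1:
            raise ValueError(f"group {self.name!r}: pph_fraction must be in [0,1]")
        if not self.diagnosis_pool:
            raise ValueError(f"group {self.name!r}: empty diagnosis pool")
        object.__setattr__(
            self,
            "diagnosis_pool",
            {normalize_icd10(c): w for c, w in self.diagnosis_pool.items()},
        )
        for dept in self.department_pool:
            if dept not in DEPARTMENTS:
                raise ValueError(f"group {self.name!r}: unknown department {dept!r}")


DEFAULT_GROUPS: tuple[LatentGroupSpec, ...] = (
    LatentGroupSpec(
        name="chronic disease",
        share=0.030,
        diagnosis_pool={"I20003": 0.25, "E11901": 0.20, "E10901": 0.05,
                        "I63900": 0.20, "I50900": 0.15, "K25901": 0.15},
        chronic_pool=("hypertension, uncomplicated", "diabetes, uncomplicated",
                      "congestive heart failure", "chronic pulmonary disease",
                      "peptic ulcer disease excluding bleeding"),
        department_pool={"internal medicine": 1.0},
        admissions_mean=3.0, admissions_dispersion=1.5,
        los_meanlog=math.log(10.0), pph_fraction=0.25,
        age_range=(45, 90), female_share=0.48,
    ),
    LatentGroupSpec(
        name="non-trauma surgery",
        share=0.013,
        diagnosis_pool={"N20001": 0.30, "K35900": 0.20, "K40902": 0.15,
                        "K80501": 0.20, "N40001": 0.05, "I83902": 0.10},
        department_pool={"surgery": 0.85, "internal medicine": 0.15},
        admissions_mean=1.6, admissions_dispersion=2.0,
        los_meanlog=math.log(8.0),
        age_range=(20, 80), female_share=0.40,
    ),
    LatentGroupSpec(
        name="female disease",
        share=0.005,
        diagnosis_pool={"D25902": 0.40, "N76002": 0.20, "N70901": 0.20,
                        "N60201": 0.20},
        department_pool={"gynecology": 0.90, "surgery": 0.10},
        admissions_mean=1.9, admissions_dispersion=2.0,
        los_meanlog=math.log(7.0),
        age_range=(20, 55), female_share=1.0,
    ),
    LatentGroupSpec(
        name="cancer",
        share=0.004,
        diagnosis_pool={"C16902": 0.25, "C18902": 0.20, "C34900": 0.25,
                        "Z51003": 0.30},
        chronic_pool=("solid tumour without metastasis",),
        department_pool={"oncology": 0.90, "internal medicine": 0.10},
        admissions_mean=4.5, admissions_dispersion=2.0,
        los_meanlog=math.log(9.0), chronic_prob=0.9,
        age_range=(40, 85), female_share=0.45, spend_multiplier=1.3,
    ),
    LatentGroupSpec(
        name="eye disease",
        share=0.004,
        diagnosis_pool={"H25901": 0.50, "H26901": 0.20, "H33001": 0.30},
        chronic_pool=("diabetes, complicated",),
        department_pool={"ophthalmology, ENT, stomatology": 1.0},
        admissions_mean=1.4, admissions_dispersion=3.0,
        los_meanlog=math.log(6.6), los_sigma=0.35, chronic_prob=0.3,
        age_range=(50, 90), female_share=0.5,
    ),
    LatentGroupSpec(
        name="respiratory infection",
        share=0.004,
        diagnosis_pool={"J15902": 0.40, "J18000": 0.40, "R50901": 0.20},
        department_pool={"pediatrics": 0.80, "internal medicine": 0.20},
        admissions_mean=2.2, admissions_dispersion=2.0,
        los_meanlog=math.log(7.0), pph_fraction=0.60,
        age_range=(0, 14), female_share=0.48,
    ),
    LatentGroupSpec(
        name="fracture",
        share=0.002,
        diagnosis_pool={"S72001": 0.40, "S82101": 0.30, "S42201": 0.30},
        department_pool={"orthopedics": 1.0},
        admissions_mean=1.2, admissions_dispersion=3.0,
        los_meanlog=math.log(12.0),
        age_range=(10, 90), female_share=0.45,
    ),
    LatentGroupSpec(
        name="liver disease",
        share=0.002,
        diagnosis_pool={"K70301": 0.30, "K74601": 0.40, "B18201": 0.30},
        chronic_pool=("liver disease",),
        department_pool={"internal medicine": 1.0},
        admissions_mean=2.5, admissions_dispersion=2.0,
        los_meanlog=math.log(10.0), chronic_prob=0.9,
        age_range=(30, 80), female_share=0.35,
    ),
    LatentGroupSpec(
        name="mental disease",
        share=0.0013,
        diagnosis_pool={"F20901": 1.0},
        chronic_pool=("psychoses", "depression"),
        department_pool={"internal medicine": 1.0},
        admissions_mean=1.8, admissions_dispersion=2.0,
        los_meanlog=math.log(32.0), los_sigma=0.30,
        age_range=(18, 70), female_share=0.5,
    ),
    LatentGroupSpec(
        name="renal failure",
        share=0.0012,
        diagnosis_pool={"N18901": 0.85, "N39001": 0.15},
        chronic_pool=("renal failure",),
        department_pool={"internal medicine": 1.0},
        admissions_mean=12.0, admissions_dispersion=3.0,
        los_meanlog=math.log(6.0), los_sigma=0.35, chronic_prob=0.9,
        pph_fraction=0.10,
        age_range=(35, 85), female_share=0.45, spend_multiplier=0.9,
    ),
)


def recovery_benchmark_groups() -> tuple[LatentGroupSpec, ...]:
    """Six well-separated planted subgroups for recovery benchmarking.

    Diagnosis pools are pairwise disjoint and each group is
    demographically coherent (one age band, one gender where clinically
    sensible, one department), so the planted structure is recoverable in
    principle and end-to-end clustering quality can be measured against
    the sidecar labels.
    """
    return (
        LatentGroupSpec(
            name="chronic disease", share=0.022,
            diagnosis_pool={"I20003": 0.3, "E11901": 0.3, "I50900": 0.2, "K25901": 0.2},
            chronic_pool=("hypertension, uncomplicated", "congestive heart failure"),
            department_pool={"internal medicine": 1.0},
            admissions_mean=3.5, admissions_dispersion=2.0,
            los_meanlog=math.log(10.0), pph_fraction=0.45,
            age_range=(65, 90), female_share=0.0, spend_multiplier=1.5),
        LatentGroupSpec(
            name="non-trauma surgery", share=0.020,
            diagnosis_pool={"N20001": 0.4, "K35900": 0.3, "K80501": 0.3},
            department_pool={"surgery": 1.0},
            admissions_mean=2.5, admissions_dispersion=2.0,
            los_meanlog=math.log(8.0), age_range=(45, 64), female_share=0.0,
            spend_multiplier=1.5),
        LatentGroupSpec(
            name="female disease", share=0.018,
            diagnosis_pool={"D25902": 0.5, "N76002": 0.5},
            department_pool={"gynecology": 1.0},
            admissions_mean=2.5, admissions_dispersion=2.0,
            los_meanlog=math.log(7.0), age_range=(15, 44), female_share=1.0,
            spend_multiplier=1.5),
        LatentGroupSpec(
            name="cancer", share=0.015,
            diagnosis_pool={"C16902": 0.4, "C34900": 0.3, "Z51003": 0.3},
            chronic_pool=("solid tumour without metastasis",),
            department_pool={"oncology": 1.0},
            admissions_mean=4.0, admissions_dispersion=2.0,
            los_meanlog=math.log(9.0), chronic_prob=0.9,
            age_range=(45, 64), female_share=1.0, spend_multiplier=1.6),
        LatentGroupSpec(
            name="eye disease", share=0.013,
            diagnosis_pool={"H25901": 0.6, "H33001": 0.4},
            department_pool={"ophthalmology, ENT, stomatology": 1.0},
            admissions_mean=2.0, admissions_dispersion=3.0,
            los_meanlog=math.log(6.6), age_range=(65, 90), female_share=1.0,
            spend_multiplier=1.8),
        LatentGroupSpec(
            name="respiratory infection", share=0.010,
            diagnosis_pool={"J15902": 0.4, "J18000": 0.4, "R50901": 0.2},
            department_pool={"pediatrics": 1.0},
            admissions_mean=2.5, admissions_dispersion=2.0,
            los_meanlog=math.log(7.0), pph_fraction=0.6,
            age_range=(0, 14), female_share=0.0, spend_multiplier=1.8),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one simulated claims population.

    The defaults describe the study conditions the pipeline is designed
    for: a three-year claims window with the last year as index year, a
    spending tail in which the top decile holds ~74% of total spending
    (``severity_sigma`` calibrated once against that share), and ten
    planted subgroups mirroring the clinical mix of a rural high-cost
    population.
    """

    n_patients: int = 20_000
    years: tuple[int, ...] = (2017, 2018, 2019)
    seed: int = 0
    severity_sigma: float = 0.85  # lognormal sigma of the patient spending multiplier
    spending_scale: float = 1.0   # global CNY scale on every encounter
    group_specs: tuple[LatentGroupSpec, ...] = DEFAULT_GROUPS
    poverty_rate_background: float = 0.16
    poverty_rate_highcost_boost: float = 0.20
    outside_county_rate: float = 0.10
    bg_admissions_mean: float = 0.42
    bg_admissions_dispersion: float = 0.35
    bg_visits_mean: float = 2.6

    def __post_init__(self) -> None:
        if self.n_patients < 100:
            raise ValueError("n_patients must be >= 100")
        for name, p in [
            ("poverty_rate_background", self.poverty_rate_background),
            ("poverty_rate_highcost_boost", self.poverty_rate_highcost_boost),
            ("outside_county_rate", self.outside_county_rate),
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        total_share = sum(g.share for g in self.group_specs)
        if total_share > 1:
            raise ValueError(f"group shares sum to {total_share:.3f} > 1")
        names = [g.name for g in self.group_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        for g in self.group_specs:
            if int(round(g.share * self.n_patients)) < 1:
                raise ValueError(
                    f"n_patients={self.n_patients} too small to realize group "
                    f"{g.name!r} (share {g.share}) with at least one patient"
                )

    @property
    def index_year(self) -> int:
        return max(self.years)


def _weighted_choice(rng, pool: dict, size: int) -> np.ndarray:
    keys = np.array(list(pool.keys()), dtype=object)
    w = np.array(list(pool.values()), dtype=float)
    return rng.choice(keys, size=size, p=w / w.sum())


def _negbin(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative binomial with given mean and shape (dispersion) parameter."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _chronic_rep_codes(elix: CodeMap) -> dict[str, str]:
    """One concrete ICD-10 code per chronic category (prefix + '902')."""
    reps: dict[str, str] = {}
    for prefix, category in elix.entries.items():
        reps.setdefault(category, prefix + "902")
    return reps


def generate_population(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a claims population.

    Returns ``(patients, encounters, latent_groups)``; the last is the
    ground-truth sidecar (``patient_id, latent_group``) with the label
    ``"background"`` for unstructured patients.  Every patient has at
    least one encounter in the index year, encounter spending decomposes
    as reimbursed + out-of-pocket, and the same config yields identical
    tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    elix = load_packaged_map("elixhauser")
    rep_codes = _chronic_rep_codes(elix)

    # --- group membership ---------------------------------------------
    group_of = np.full(n, -1, dtype=int)  # -1 = background
    perm = rng.permutation(n)
    pos = 0
    for gi, g in enumerate(config.group_specs):
        size = int(round(g.share * n))
        group_of[perm[pos : pos + size]] = gi
        pos += size

    # --- demographics --------------------------------------------------
    age = np.clip(np.round(rng.normal(42, 23, size=n)), 0, 100).astype(int)
    female = rng.random(n) < 0.515
    for gi, g in enumerate(config.group_specs):
        m = group_of == gi
        k = int(m.sum())
        age[m] = rng.integers(g.age_range[0], g.age_range[1] + 1, size=k)
        female[m] = rng.random(k) < g.female_share
    severity = np.exp(rng.normal(0.0, config.severity_sigma, size=n))
    severity[group_of >= 0] = np.exp(rng.normal(0.6, 0.35, size=int((group_of >= 0).sum())))

    # poverty is more prevalent among prospective high-cost patients
    # (planted group members and the high-severity background tail)
    poverty_p = np.full(n, config.poverty_rate_background)
    likely_high_cost = (group_of >= 0) | (severity >= np.quantile(severity, 0.90))
    poverty_p[likely_high_cost] += config.poverty_rate_highcost_boost
    poverty = rng.random(n) < poverty_p

    # --- chronic conditions (persist over all years) -------------------
    chronic_pat: list[np.ndarray] = []
    chronic_code: list[np.ndarray] = []
    bg_idx = np.nonzero(group_of == -1)[0]
    for category, p in _BG_CHRONIC.items():
        has = bg_idx[rng.random(len(bg_idx)) < p]
        chronic_pat.append(has)
        chronic_code.append(np.full(len(has), rep_codes[category], dtype=object))
    for gi, g in enumerate(config.group_specs):
        gidx = np.nonzero(group_of == gi)[0]
        for j, category in enumerate(g.chronic_pool):
            if category not in rep_codes:
                raise ValueError(
                    f"group {g.name!r}: chronic category {category!r} not in the "
                    "chronic-condition map"
                )
            p = g.chronic_prob * (0.5 ** j)
            has = gidx[rng.random(len(gidx)) < p]
            chronic_pat.append(has)
            chronic_code.append(np.full(len(has), rep_codes[category], dtype=object))
    chr_pat = np.concatenate(chronic_pat) if chronic_pat else np.array([], dtype=int)
    chr_code = np.concatenate(chronic_code) if chronic_code else np.array([], dtype=object)

    # --- index-year utilization counts ---------------------------------
    admissions = _negbin(rng, config.bg_admissions_mean, config.bg_admissions_dispersion, n)
    visits = rng.poisson(config.bg_visits_mean, size=n)
    for gi, g in enumerate(config.group_specs):
        m = group_of == gi
        k = int(m.sum())
        admissions[m] = np.maximum(1, _negbin(rng, g.admissions_mean, g.admissions_dispersion, k))
        visits[m] = 1 + rng.poisson(3.0, size=k)
    # every patient utilizes something in the index year
    lonely = (admissions == 0) & (visits == 0)
    visits[lonely] = 1

    parts: list[dict[str, np.ndarray]] = []

    # --- admissions (index year) ---------------------------------------
    adm_pat = np.repeat(np.arange(n), admissions)
    n_adm = len(adm_pat)
    adm_group = group_of[adm_pat]
    dx = _weighted_choice(rng, _BG_ADMIT_DX, n_adm)
    dept = _weighted_choice(
        rng,
        {"internal medicine": 0.40, "surgery": 0.22, "orthopedics": 0.10,
         "gynecology": 0.06, "obstetrics": 0.04, "pediatrics": 0.08,
         "oncology": 0.03, "ophthalmology, ENT, stomatology": 0.04,
         "rehabilitation": 0.03},
        n_adm,
    )
    los = np.exp(rng.normal(math.log(7.0), 0.6, size=n_adm))
    mult = np.ones(n_adm)
    for gi, g in enumerate(config.group_specs):
        m = adm_group == gi
        k = int(m.sum())
        if k == 0:
            continue
        dx[m] = _weighted_choice(rng, g.diagnosis_pool, k)
        dept[m] = _weighted_choice(rng, g.department_pool, k)
        los[m] = np.exp(rng.normal(g.los_meanlog, g.los_sigma, size=k))
        mult[m] = g.spend_multiplier
    los = np.clip(np.round(los), 1, 365).astype(int)
    base = np.array([_DEPT_BASE_CNY[d] for d in dept])
    spend = (
        config.spending_scale * mult * base * (0.5 + 0.08 * los)
        * np.exp(rng.normal(0.0, 0.45, size=n_adm)) * severity[adm_pat]
    )
    parts.append(
        dict(pat=adm_pat, etype=np.full(n_adm, "inpatient", dtype=object),
             year=np.full(n_adm, config.index_year), dx=dx, dept=dept,
             in_county=rng.random(n_adm) >= config.outside_county_rate,
             los=los, total=spend)
    )

    # --- outpatient visits (index year) --------------------------------
    vis_pat = np.repeat(np.arange(n), visits)
    n_vis = len(vis_pat)
    vspend = (
        config.spending_scale * 80.0
        * np.exp(rng.normal(0.0, 0.8, size=n_vis))
        * severity[vis_pat] ** 0.5
    )
    # active diagnoses track the underlying condition: group members'
    # visits mostly carry their own group's diagnoses
    vis_dx = _weighted_choice(rng, _BG_VISIT_DX, n_vis)
    vis_group = group_of[vis_pat]
    for gi, g in enumerate(config.group_specs):
        m = (vis_group == gi) & (rng.random(n_vis) < 0.7)
        k = int(m.sum())
        if k:
            vis_dx[m] = _weighted_choice(rng, g.diagnosis_pool, k)
    parts.append(
        dict(pat=vis_pat, etype=np.full(n_vis, "outpatient", dtype=object),
             year=np.full(n_vis, config.index_year),
             dx=vis_dx,
             dept=np.full(n_vis, "internal medicine", dtype=object),
             in_county=rng.random(n_vis) >= config.outside_county_rate / 20,
             los=np.zeros(n_vis, dtype=int), total=vspend)
    )

    # --- prior-year chronic-condition visits ---------------------------
    prior_years = [y for y in config.years if y != config.index_year]
    for y in prior_years:
        seen = rng.random(len(chr_pat)) < 0.8
        cp, cc = chr_pat[seen], chr_code[seen]
        k = len(cp)
        parts.append(
            dict(pat=cp, etype=np.full(k, "outpatient", dtype=object),
                 year=np.full(k, y), dx=cc,
                 dept=np.full(k, "internal medicine", dtype=object),
                 in_county=np.ones(k, dtype=bool),
                 los=np.zeros(k, dtype=int),
                 total=config.spending_scale * 50.0
                 * np.exp(rng.normal(0.0, 0.6, size=k)))
        )

    # --- assemble ------------------------------------------------------
    cat = {key: np.concatenate([p[key] for p in parts]) for key in parts[0]}
    total = np.round(cat["total"], 2)
    oop = np.round(total * rng.uniform(0.25, 0.55, size=len(total)), 2)
    width = len(str(n))
    pid = np.array([f"P{str(i).zfill(width)}" for i in range(n)], dtype=object)

    encounters = pd.DataFrame(
        {
            "patient_id": pid[cat["pat"]],
            "encounter_type": cat["etype"],
            "year": cat["year"].astype(int),
            "principal_dx": cat["dx"],
            "department": cat["dept"],
            "in_county": cat["in_county"].astype(bool),
            "los_days": cat["los"].astype(int),
            "total_spend": total,
            "oop_spend": oop,
        }
    )
    encounters = encounters.sort_values(
        ["patient_id", "year", "encounter_type"], kind="stable"
    ).reset_index(drop=True)
    encounters.insert(
        0, "encounter_id",
        [f"E{str(i).zfill(width + 2)}" for i in range(len(encounters))],
    )

    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "age": age,
            "gender": np.where(female, "female", "male"),
            "poverty": poverty,
        }
    )
    group_names = np.array(
        ["background"] + [g.name for g in config.group_specs], dtype=object
    )
    latent = pd.DataFrame(
        {"patient_id": pid, "latent_group": group_names[group_of + 1]}
    )

    # rewrite principal diagnoses so each group's admissions carry an
    # ambulatory-care-sensitive code at its configured rate
    pqi = load_packaged_map("pqi")
    encounters = plant_pph_admissions(
        encounters, config.group_specs, pqi, latent,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return patients, encounters, latent


def plant_pph_admissions(
    encounters: pd.DataFrame,
    group_specs: tuple[LatentGroupSpec, ...] | list[LatentGroupSpec],
    code_list: CodeMap,
    latent_groups: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Resample each group's admission diagnoses to hit its PPH rate.

    For every group with ``pph_fraction = p``, each of its admissions
    independently (probability *p*) receives a principal diagnosis drawn
    from the PPH-eligible part of the group's diagnosis pool, otherwise
    from the non-eligible part.  Rejects groups whose pool cannot supply
    the required side (e.g. pool disjoint from the code list while
    ``p > 0``).
    """
    if not code_list.entries:
        raise ValueError("empty PPH code list")
    rng = np.random.default_rng(seed)
    enc = encounters.copy()
    glabel = enc["patient_id"].map(
        latent_groups.set_index("patient_id")["latent_group"]
    )
    is_adm = (enc["encounter_type"] == "inpatient").to_numpy()

    for g in group_specs:
        eligible = {c: w for c, w in g.diagnosis_pool.items()
                    if code_list.classify(c) is not None}
        other = {c: w for c, w in g.diagnosis_pool.items() if c not in eligible}
        if g.pph_fraction > 0 and not eligible:
            raise ValueError(
                f"group {g.name!r}: pph_fraction={g.pph_fraction} but its "
                "diagnosis pool is disjoint from the PPH code list"
            )
        if g.pph_fraction < 1 and not other:
            raise ValueError(
                f"group {g.name!r}: pph_fraction={g.pph_fraction} < 1 but "
                "every pool diagnosis is PPH-eligible"
            )
        m = (is_adm & (glabel == g.name).to_numpy()).nonzero()[0]
        if len(m) == 0:
            continue
        take_pph = rng.random(len(m)) < g.pph_fraction
        dx = np.empty(len(m), dtype=object)
        if take_pph.any():
            dx[take_pph] = _weighted_choice(rng, eligible, int(take_pph.sum()))
        if (~take_pph).any():
            dx[~take_pph] = _weighted_choice(rng, other, int((~take_pph).sum()))
        enc.iloc[m, enc.columns.get_loc("principal_dx")] = dx
    return enc
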