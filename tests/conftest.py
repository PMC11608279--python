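import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hicost import (
    SimConfig,
    build_features,
    deduplicate,
    filter_low_prevalence,
    generate_population,
    load_packaged_map,
    select_high_cost,
    summarize_patient_year,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

INDEX_YEAR = 2019


@pytest.fixture(scope="session")
def maps():
    return {
        "adrg": load_packaged_map("adrg"),
        "elixhauser": load_packaged_map("elixhauser"),
        "pqi": load_packaged_map("pqi"),
    }


@pytest.fixture(scope="session")
def pop20k():
    """Default-condition population of 20 000 patients with its sidecar."""
    patients, encounters, latent = generate_population(
        SimConfig(n_patients=20_000, seed=11)
    )
    return patients, encounters, latent


@pytest.fixture(scope="session")
def summaries20k(pop20k):
    patients, encounters, _ = pop20k
    s = summarize_patient_year(encounters, patients, INDEX_YEAR)
    return select_high_cost(s, 0.10)


@pytest.fixture(scope="session")
def features20k(pop20k, summaries20k, maps):
    patients, encounters, _ = pop20k
    enc_year = encounters[encounters["year"] == INDEX_YEAR]
    fm = build_features(
        summaries20k, enc_year, encounters, patients, maps["adrg"], maps["elixhauser"]
    )
    return filter_low_prevalence(fm)


@pytest.fixture(scope="session")
def dedup20k(features20k):
    return deduplicate(features20k)


@pytest.fixture(scope="session")
def labels20k(dedup20k):
    """Cluster labels for the 20k population, propagated to patients."""
    from hicost import optics_cluster, pca_reduce, propagate_labels, tsne_embed

    emb = tsne_embed(pca_reduce(dedup20k.unique), seed=1)
    sol = optics_cluster(emb, dedup20k)
    return propagate_labels(sol, dedup20k)


@pytest.fixture()
def tiny_encounters():
    """Hand-written encounter table with known aggregates."""
    rows = [
        # patient A: two admissions (5d, 15d) and one visit
        ("e1", "A", "inpatient", 2019, "I10002", "internal medicine", True, 5, 1000.0, 400.0),
        ("e2", "A", "inpatient", 2019, "I50900", "internal medicine", False, 15, 3000.0, 1200.0),
        ("e3", "A", "outpatient", 2019, "J06900", "internal medicine", True, 0, 50.0, 20.0),
        # patient B: outpatient only
        ("e4", "B", "outpatient", 2019, "K29700", "internal medicine", True, 0, 80.0, 30.0),
        # patient C: one admission in a prior year only
        ("e5", "C", "inpatient", 2018, "S72001", "orthopedics", True, 10, 2000.0, 900.0),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "encounter_id", "patient_id", "encounter_type", "year", "principal_dx",
            "department", "in_county", "los_days", "total_spend", "oop_spend",
        ],
    )


@pytest.fixture()
def tiny_patients():
    return pd.DataFrame(
        {
            "patient_id": ["A", "B", "C"],
            "age": [70, 30, 50],
            "gender": ["male", "female", "male"],
            "poverty": [True, False, False],
        }
    )
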