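"""Cluster characterization: standardized ratios and expert subgroup merges.

A cluster is described by the ratio of its mean to the whole clustering
population's mean for every clustering variable; ratios far above 1 mark
the variables on which the cluster deviates most, and the top few become
its *distinguishing factors* (with their source category attached).
Clinically similar clusters are then merged into larger subgroups by an
externally supplied many-to-one map (expert judgment is an input here,
not something the package attempts to automate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .segmentation import NOISE

__all__ = [
    "ClusterProfile",
    "standardized_ratios",
    "distinguishing_factors",
    "load_subgroup_map",
    "apply_subgroup_map",
]


@dataclass
class ClusterProfile:
    """Per-variable means and standardized ratios for one cluster."""

    cluster: int
    n_patients: int
    table: pd.DataFrame  # columns: variable, source, cluster_mean, population_mean, ratio


def standardized_ratios(
    patient_labels: pd.Series,
    fm: FeatureMatrix,
) -> list[ClusterProfile]:
    """Ratios of cluster means to population means for every variable.

    The population is every patient entering clustering (noise included),
    so size-weighted cluster means — with noise as its own bucket — equal
    the population mean for each variable.  Variables with a zero
    population mean get NaN ratios (flagged, never silently 0).
    """
    m = fm.matrix.loc[patient_labels.index]
    pop_mean = m.mean()
    profiles = []
    for c in sorted(set(patient_labels) - {NOISE}):
        members = m[patient_labels == c]
        cmean = members.mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(pop_mean > 0, cmean / pop_mean, np.nan)
        profiles.append(
            ClusterProfile(
                cluster=int(c),
                n_patients=len(members),
                table=pd.DataFrame(
                    {
                        "variable": m.columns,
                        "source": [fm.sources[v] for v in m.columns],
                        "cluster_mean": cmean.to_numpy(),
                        "population_mean": pop_mean.to_numpy(),
                        "ratio": ratio,
                    }
                ),
            )
        )
    return profiles


def distinguishing_factors(
    profiles: list[ClusterProfile], k: int = 5
) -> pd.DataFrame:
    """Top-k variables by standardized ratio for each cluster.

    Ties on the ratio break by cluster mean (descending) then variable
    name; fewer than k finite ratios returns what exists.
    """
    rows = []
    for p in profiles:
        t = p.table.dropna(subset=["ratio"]).sort_values(
            ["ratio", "cluster_mean", "variable"],
            ascending=[False, False, True],
            kind="stable",
        )
        for rank, (_, r) in enumerate(t.head(k).iterrows(), start=1):
            rows.append(
                {
                    "cluster": p.cluster,
                    "rank": rank,
                    "variable": r["variable"],
                    "category": r["source"],
                    "ratio": r["ratio"],
                    "cluster_mean": r["cluster_mean"],
                }
            )
    return pd.DataFrame(rows)


def load_subgroup_map(path) -> dict[int, str]:
    """Read a cluster -> subgroup merge map (CSV: cluster_id, subgroup)."""
    df = pd.read_csv(path)
    missing = {"cluster_id", "subgroup"} - set(df.columns)
    if missing:
        raise ValueError(f"subgroup map missing columns: {sorted(missing)}")
    return dict(zip(df["cluster_id"].astype(int), df["subgroup"].astype(str)))


def apply_subgroup_map(
    patient_labels: pd.Series, subgroup_map: dict[int, str]
) -> pd.Series:
    """Relabel clusters into subgroups (noise stays noise).

    A pure relabeling: total labeled count is conserved, and any
    non-noise cluster absent from the map raises with its id.
    """
    clusters = set(int(c) for c in patient_labels.unique()) - {NOISE}
    unmapped = clusters - set(subgroup_map)
    if unmapped:
        raise ValueError(f"subgroup map does not cover clusters: {sorted(unmapped)}")
    out = patient_labels.map(lambda c: "noise" if c == NOISE else subgroup_map[int(c)])
    out.name = "subgroup"
    return out
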