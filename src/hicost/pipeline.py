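"""One-command orchestration: simulate -> cohort -> features -> segment
-> profile -> preventable cost -> reports.

Every stage writes its intermediate to the artifact directory
(restartable, inspectable), and a manifest records the config hash, the
master seed and library versions so any run can be reproduced
byte-for-byte.  All randomized stages draw their seeds from the single
``master_seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import claims as _claims
from . import cohort as _cohort
from . import features as _features
from . import pph as _pph
from . import profiling as _profiling
from . import segmentation as _segmentation
from . import synthetic as _synthetic
from .codes import load_code_map, load_packaged_map

__all__ = ["PipelineConfig", "validate_config", "run_all"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Typed pipeline configuration (see ``examples/`` for a YAML sample)."""

    out_dir: str = "hicost_run"
    claims_dir: str | None = None          # load claims from here ...
    simulate_n_patients: int | None = 20_000  # ... or simulate when None
    year: int = 2019
    high_cost_fraction: float = 0.10
    adrg_min_prevalence: float = 0.01
    comorbidity_min_prevalence: float = 0.001
    pca_variance_target: float = 0.80
    tsne_perplexity: float = 30.0
    tsne_theta: float = 0.5
    tsne_max_iter: int = 1000
    optics_min_samples: tuple[int, ...] = (10, 20, 40, 80)
    optics_xi: tuple[float, ...] = (0.01, 0.02, 0.05)
    min_clusters: int = 5
    min_cluster_share: float = 0.01
    run_comparators: bool = False
    merge_map_path: str | None = None
    adrg_map_path: str | None = None
    elixhauser_map_path: str | None = None
    pqi_map_path: str | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if not 0 < self.high_cost_fraction < 1:
            errors.append("high_cost_fraction must be in (0,1)")
        if not 0 < self.pca_variance_target <= 1:
            errors.append("pca_variance_target must be in (0,1]")
        if self.tsne_perplexity <= 0:
            errors.append("tsne_perplexity must be positive")
        for name in ("merge_map_path", "adrg_map_path", "elixhauser_map_path",
                     "pqi_map_path", "claims_dir"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                errors.append(f"{name} does not exist: {p}")
        if self.claims_dir is None and self.simulate_n_patients is None:
            errors.append("either claims_dir or simulate_n_patients is required")
        if errors:
            raise ValueError("invalid pipeline config: " + "; ".join(errors))


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys (typo?): {sorted(unknown)}")
    for key in ("optics_min_samples", "optics_xi"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(**raw)
    if cfg.claims_dir is not None:
        ppath = Path(cfg.claims_dir) / "patients.csv"
        if ppath.exists():
            n = sum(1 for _ in open(ppath)) - 1
            if cfg.tsne_perplexity >= n / 3:
                raise ValueError(
                    f"tsne_perplexity={cfg.tsne_perplexity} >= n/3 for the "
                    f"{n} patients in {ppath}"
                )
    return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(cfg: PipelineConfig) -> Path:
    """Run every stage and return the artifact directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.master_seed)
    seeds = {k: int(rng.integers(0, 2**31 - 1))
             for k in ("simulate", "tsne", "pam", "ridge")}

    adrg = (load_code_map(cfg.adrg_map_path, "adrg") if cfg.adrg_map_path
            else load_packaged_map("adrg"))
    elix = (load_code_map(cfg.elixhauser_map_path, "elixhauser")
            if cfg.elixhauser_map_path else load_packaged_map("elixhauser"))
    pqi = (load_code_map(cfg.pqi_map_path, "pqi") if cfg.pqi_map_path
           else load_packaged_map("pqi"))

    # --- stage 1: claims -------------------------------------------------
    if cfg.claims_dir is not None:
        bundle = _claims.read_claims(cfg.claims_dir, reject_path=out / "rejects")
        patients, encounters = bundle.patients, bundle.encounters
    else:
        sim = _synthetic.SimConfig(
            n_patients=cfg.simulate_n_patients, seed=seeds["simulate"]
        )
        patients, encounters, latent = _synthetic.generate_population(sim)
        _claims.write_claims(patients, encounters, out / "claims", latent)
    log.info("stage claims: %d patients, %d encounters", len(patients), len(encounters))

    # --- stage 2: cohort -------------------------------------------------
    summaries = _cohort.summarize_patient_year(encounters, patients, cfg.year)
    summaries = _cohort.select_high_cost(summaries, cfg.high_cost_fraction)
    summaries.to_csv(out / "patient_year_summaries.csv", index=False)

    # --- stage 3: features ----------------------------------------------
    enc_year = encounters[encounters["year"] == cfg.year]
    fm = _features.build_features(summaries, enc_year, encounters, patients, adrg, elix)
    fm = _features.filter_low_prevalence(
        fm, cfg.adrg_min_prevalence, cfg.comorbidity_min_prevalence
    )
    dedup = _features.deduplicate(fm)
    fm.matrix.to_csv(out / "features.csv")
    meta = {
        c: {"source": fm.sources[c], "prevalence": float(fm.prevalence[c])}
        for c in fm.matrix.columns
    }
    (out / "features_meta.json").write_text(json.dumps(meta, indent=1))
    _cohort.cohort_table(
        summaries, patients,
        chronic_flags=fm.matrix[fm.columns_of("comorbidity")],
        adrg_flags=fm.matrix[fm.columns_of("ADRG")],
    ).to_csv(out / "cohort_table.csv", index=False)

    # --- stage 4: segmentation ------------------------------------------
    emb = _segmentation.pca_reduce(dedup.unique, cfg.pca_variance_target)
    emb = _segmentation.tsne_embed(
        emb,
        perplexity=cfg.tsne_perplexity,
        seed=seeds["tsne"],
        theta=cfg.tsne_theta,
        max_iter=cfg.tsne_max_iter,
    )
    best, candidates = _segmentation.optics_cluster(
        emb, dedup,
        {"min_samples": cfg.optics_min_samples, "xi": cfg.optics_xi},
        cfg.min_clusters, cfg.min_cluster_share,
        return_all=True,
    )
    labels = _segmentation.propagate_labels(best, dedup)
    labels.rename("cluster").to_csv(out / "cluster_labels.csv")
    solution = {
        "algorithm": best.algorithm,
        "params": best.params,
        "n_clusters": best.n_clusters,
        "noise_share": best.noise_share,
        "cluster_sizes": {str(k): v for k, v in best.cluster_sizes.items()},
        "constraints_ok": best.constraints_ok,
        "pca_components": emb.n_components,
        "pca_cumulative_variance": emb.cumulative_variance,
        "tsne_params": emb.tsne_params,
        "candidates": [
            {"params": c.params, "n_clusters": c.n_clusters,
             "constraints_ok": c.constraints_ok, "notes": c.constraint_notes}
            for c in candidates
        ],
    }
    solutions = [best]
    if cfg.run_comparators:
        comps = _segmentation.comparator_clusterings(
            emb, range(cfg.min_clusters, cfg.min_clusters + 8), dedup,
            cfg.min_clusters, cfg.min_cluster_share, seed=seeds["pam"],
        )
        solutions += comps
        evaluation = _segmentation.evaluate_solutions(
            solutions, dedup.unique, seed=seeds["ridge"]
        )
        evaluation.to_csv(out / "solution_evaluation.csv", index=False)
    (out / "solution.json").write_text(json.dumps(solution, indent=1))
    _plot_embedding(emb.coords, best.labels, out / "embedding.png")

    # --- stage 5: profiling ---------------------------------------------
    profiles = _profiling.standardized_ratios(labels, fm)
    factors = _profiling.distinguishing_factors(profiles)
    factors.to_csv(out / "distinguishing_factors.csv", index=False)
    if cfg.merge_map_path is not None:
        merge = _profiling.load_subgroup_map(cfg.merge_map_path)
        subgroups = _profiling.apply_subgroup_map(labels, merge)
    else:
        log.warning("no merge map supplied; reporting per-cluster subgroups")
        subgroups = labels.map(lambda c: "noise" if c == -1 else f"cluster {c}")
        subgroups.name = "subgroup"
    subgroups.to_csv(out / "subgroup_labels.csv")

    # --- stage 6: preventable inpatient cost ----------------------------
    flags = _pph.flag_pph(enc_year, pqi)
    pic = _pph.compute_pic(flags, enc_year)
    pic.to_csv(out / "patient_pic.csv")
    report = _pph.subgroup_report(subgroups, summaries, pic)
    report.to_csv(out / "subgroup_report.csv", index=False)
    cluster_report = _pph.subgroup_report(
        labels.map(lambda c: "noise" if c == -1 else f"cluster {c}"), summaries, pic
    )
    cluster_report.to_csv(out / "cluster_report.csv", index=False)

    # --- manifest --------------------------------------------------------
    import sklearn

    manifest = {
        "config": dataclasses.asdict(cfg),
        "config_hash": _config_hash(cfg),
        "master_seed": cfg.master_seed,
        "stage_seeds": seeds,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


def _plot_embedding(coords: np.ndarray, labels: np.ndarray, path: Path) -> None:
    """Scatter of the 2-D embedding colored by cluster (noise in grey)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    noise = labels == -1
    ax.scatter(coords[noise, 0], coords[noise, 1], s=4, c="lightgrey", label="noise")
    for c in sorted(set(labels) - {-1}):
        m = labels == c
        ax.scatter(coords[m, 0], coords[m, 1], s=4, label=f"cluster {c}")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    if len(set(labels)) <= 16:
        ax.legend(markerscale=2, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
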