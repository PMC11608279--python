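"""Dimension reduction and constrained clustering of the feature matrix.

The segmentation follows a three-stage recipe common in data-driven
patient taxonomy work:

1. **PCA** on standardized binary columns, keeping the smallest number of
   components whose cumulative explained variance reaches a target
   (default 80%);
2. **Barnes-Hut t-SNE** of the component scores down to 2-D (perplexity
   30, theta 0.5 by default; all exposed);
3. **OPTICS** (xi extraction) on the 2-D embedding, grid-searched over
   ``min_samples`` and ``xi`` and restricted to *operationally
   meaningful* solutions: at least five clusters, each holding at least
   1% of the high-cost patients (cluster shares are measured after
   expanding deduplicated rows back to patients).  Among compliant
   solutions the one clustering the largest patient share wins; ties go
   to fewer clusters.

Ward-linkage hierarchical clustering and PAM k-medoids run as
comparators over a k range with the same constraint flags, and a set of
one-vs-rest ridge models measures how separable each solution's clusters
are in the original clinical variables (cross-validated AUC; ~0.5 for
arbitrary labels, near 1 for clinically coherent clusters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import OPTICS, AgglomerativeClustering
from sklearn.decomposition import PCA
from sklearn.linear_model import RidgeClassifier
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.preprocessing import StandardScaler

from .features import DedupResult, FeatureMatrix

__all__ = [
    "EmbeddingResult",
    "ClusterSolution",
    "ConstraintError",
    "pca_reduce",
    "tsne_embed",
    "optics_cluster",
    "comparator_clusterings",
    "evaluate_solutions",
    "propagate_labels",
    "recovery_ari",
]

log = logging.getLogger(__name__)

NOISE = -1

DEFAULT_OPTICS_GRID = {
    "min_samples": (10, 20, 40, 80),
    "xi": (0.01, 0.02, 0.05),
}


@dataclass
class EmbeddingResult:
    """PCA scores and (optionally) the 2-D t-SNE coordinates."""

    scores: np.ndarray
    n_components: int
    cumulative_variance: float
    coords: np.ndarray | None = None
    tsne_params: dict = field(default_factory=dict)


@dataclass
class ClusterSolution:
    """One clustering of the unique feature rows.

    ``labels`` are per unique row (noise = -1); sizes and shares refer to
    patients after expansion through the dedup multiplicities.
    """

    labels: np.ndarray
    algorithm: str
    params: dict
    n_clusters: int
    cluster_sizes: dict[int, int]
    noise_share: float
    clustered_share: float
    constraints_ok: bool
    constraint_notes: str = ""


class ConstraintError(RuntimeError):
    """No clustering solution satisfied the imposed constraints."""


def pca_reduce(fm: FeatureMatrix | pd.DataFrame, variance_target: float = 0.80) -> EmbeddingResult:
    """Standardize columns and keep the fewest components reaching the target.

    Columns are centered and scaled first so high-prevalence binaries do
    not dominate the leading eigenvectors.
    """
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    m = fm.matrix if isinstance(fm, FeatureMatrix) else fm
    if m.shape[1] < 2 or m.shape[0] < 3:
        raise ValueError("need at least 3 rows and 2 columns for PCA")
    x = StandardScaler().fit_transform(m.to_numpy(dtype=float))
    pca = PCA(svd_solver="full").fit(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, len(cum))
    scores = pca.transform(x)[:, :k]
    return EmbeddingResult(
        scores=scores, n_components=k, cumulative_variance=float(cum[k - 1])
    )


def tsne_embed(
    embedding: EmbeddingResult,
    perplexity: float = 30.0,
    seed: int = 0,
    theta: float = 0.5,
    max_iter: int = 1000,
) -> EmbeddingResult:
    """Barnes-Hut t-SNE of the PCA scores down to 2-D (deterministic per seed)."""
    n = embedding.scores.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(
            f"perplexity={perplexity} too large for n={n}; need n > 3*perplexity "
            "(reduce perplexity or supply more rows)"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        angle=theta,
        method="barnes_hut",
        max_iter=max_iter,
        init="pca",
        random_state=seed,
    )
    coords = tsne.fit_transform(embedding.scores)
    if not np.isfinite(coords).all():
        raise RuntimeError("t-SNE produced non-finite coordinates")
    return EmbeddingResult(
        scores=embedding.scores,
        n_components=embedding.n_components,
        cumulative_variance=embedding.cumulative_variance,
        coords=coords,
        tsne_params={"perplexity": perplexity, "seed": seed, "theta": theta,
                     "max_iter": max_iter},
    )


def _solution_from_labels(
    labels: np.ndarray,
    algorithm: str,
    params: dict,
    multiplicity: np.ndarray,
    min_clusters: int,
    min_share: float,
) -> ClusterSolution:
    total = int(multiplicity.sum())
    ids = sorted(c for c in np.unique(labels) if c != NOISE)
    sizes = {int(c): int(multiplicity[labels == c].sum()) for c in ids}
    noise = int(multiplicity[labels == NOISE].sum())
    notes = []
    if len(ids) < min_clusters:
        notes.append(f"only {len(ids)} clusters (< {min_clusters})")
    small = [c for c, s in sizes.items() if s / total < min_share]
    if small:
        notes.append(f"{len(small)} clusters below {min_share:.0%} patient share")
    return ClusterSolution(
        labels=labels,
        algorithm=algorithm,
        params=params,
        n_clusters=len(ids),
        cluster_sizes=sizes,
        noise_share=noise / total,
        clustered_share=1 - noise / total,
        constraints_ok=not notes,
        constraint_notes="; ".join(notes),
    )


def optics_cluster(
    embedding: EmbeddingResult,
    dedup: DedupResult | None = None,
    param_grid: dict = DEFAULT_OPTICS_GRID,
    min_clusters: int = 5,
    min_share: float = 0.01,
    return_all: bool = False,
) -> ClusterSolution | tuple[ClusterSolution, list[ClusterSolution]]:
    """Grid-searched OPTICS on the 2-D embedding under solution constraints.

    Raises :class:`ConstraintError` (listing the nearest misses) when no
    grid point yields a compliant solution.
    """
    coords = embedding.coords
    if coords is None:
        raise ValueError("embedding has no 2-D coordinates; run tsne_embed first")
    if not param_grid.get("min_samples") or not param_grid.get("xi"):
        raise ValueError("param_grid must provide min_samples and xi values")
    mult = (
        dedup.multiplicity.to_numpy()
        if dedup is not None
        else np.ones(len(coords), dtype=int)
    )
    candidates: list[ClusterSolution] = []
    for min_samples in param_grid["min_samples"]:
        if min_samples >= len(coords):
            log.warning("skipping min_samples=%d >= n=%d", min_samples, len(coords))
            continue
        for xi in param_grid["xi"]:
            labels = OPTICS(
                min_samples=min_samples, xi=xi, cluster_method="xi"
            ).fit_predict(coords)
            sol = _solution_from_labels(
                labels, "optics", {"min_samples": min_samples, "xi": xi},
                mult, min_clusters, min_share,
            )
            candidates.append(sol)
    compliant = [s for s in candidates if s.constraints_ok]
    if not compliant:
        misses = "; ".join(
            f"{s.params}: {s.constraint_notes}" for s in candidates[:6]
        )
        raise ConstraintError(
            f"no OPTICS solution met >= {min_clusters} clusters with >= "
            f"{min_share:.0%} patient share each; nearest misses: {misses}"
        )
    best = max(compliant, key=lambda s: (s.clustered_share, -s.n_clusters))
    return (best, candidates) if return_all else best


def _pam_kmedoids(coords: np.ndarray, k: int, seed: int, max_iter: int = 50) -> np.ndarray:
    """Seeded PAM (build + swap-by-alternation) k-medoids on 2-D points."""
    rng = np.random.default_rng(seed)
    n = len(coords)
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(max_iter):
        d = cdist(coords, coords[medoids])
        labels = d.argmin(axis=1)
        new_medoids = medoids.copy()
        for j in range(k):
            members = np.nonzero(labels == j)[0]
            if len(members) == 0:
                continue
            intra = cdist(coords[members], coords[members]).sum(axis=1)
            new_medoids[j] = members[intra.argmin()]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    return cdist(coords, coords[medoids]).argmin(axis=1)


def comparator_clusterings(
    embedding: EmbeddingResult,
    k_range: range | tuple[int, ...] = range(5, 16),
    dedup: DedupResult | None = None,
    min_clusters: int = 5,
    min_share: float = 0.01,
    seed: int = 0,
) -> list[ClusterSolution]:
    """Ward hierarchical and PAM k-medoids solutions over a k range.

    The same constraint flags as for OPTICS are attached; k values
    exceeding the number of unique rows are skipped with a warning.
    """
    coords = embedding.coords
    if coords is None:
        raise ValueError("embedding has no 2-D coordinates; run tsne_embed first")
    mult = (
        dedup.multiplicity.to_numpy()
        if dedup is not None
        else np.ones(len(coords), dtype=int)
    )
    out: list[ClusterSolution] = []
    for k in k_range:
        if k > len(coords):
            log.warning("skipping k=%d > %d unique rows", k, len(coords))
            continue
        ward = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(coords)
        out.append(
            _solution_from_labels(ward, "hierarchical_ward", {"k": k}, mult,
                                  min_clusters, min_share)
        )
        pam = _pam_kmedoids(coords, k, seed=seed)
        out.append(
            _solution_from_labels(pam, "kmedoids_pam", {"k": k, "seed": seed}, mult,
                                  min_clusters, min_share)
        )
    return out


def evaluate_solutions(
    solutions: list[ClusterSolution],
    clinical: FeatureMatrix | pd.DataFrame,
    min_members: int = 10,
    cv: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical separability of each solution via one-vs-rest ridge models.

    For every cluster with at least ``min_members`` unique rows, a ridge
    classifier predicts membership from the clinical variables under
    stratified cross-validation; the table reports the mean and SD of the
    per-cluster AUCs.  Random labels score ~0.5, clinically coherent
    clusters near 1.
    """
    m = clinical.matrix if isinstance(clinical, FeatureMatrix) else clinical
    x = m.to_numpy(dtype=float)
    rows = []
    for i, sol in enumerate(solutions):
        aucs = []
        for c in sorted(sol.cluster_sizes):
            y = (sol.labels == c).astype(int)
            if y.sum() < min_members:
                log.warning("solution %d: cluster %d has <%d members; excluded",
                            i, c, min_members)
                continue
            skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
            scores = cross_val_score(
                RidgeClassifier(), x, y, scoring="roc_auc", cv=skf
            )
            aucs.append(scores.mean())
        rows.append(
            {
                "algorithm": sol.algorithm,
                "params": str(sol.params),
                "n_clusters": sol.n_clusters,
                "constraints_ok": sol.constraints_ok,
                "mean_auc": float(np.mean(aucs)) if aucs else np.nan,
                "sd_auc": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else np.nan,
                "n_evaluated_clusters": len(aucs),
            }
        )
    return pd.DataFrame(rows)


def propagate_labels(solution: ClusterSolution, dedup: DedupResult) -> pd.Series:
    """Expand unique-row cluster labels to every patient via the dedup map."""
    by_row = pd.Series(solution.labels, index=dedup.unique.index)
    if dedup.representative.isna().any():
        raise ValueError("dedup map leaves some patients unmapped")
    labels = dedup.representative.map(by_row)
    if labels.isna().any():
        missing = labels[labels.isna()].index[:5].tolist()
        raise ValueError(f"patients mapped to unknown unique rows: {missing}")
    labels.name = "cluster"
    return labels.astype(int)


def recovery_ari(
    patient_labels: pd.Series,
    latent_groups: pd.DataFrame,
    include_noise: bool = False,
    planted_only: bool = True,
    background_label: str = "background",
) -> float:
    """Adjusted Rand index between recovered clusters and planted groups.

    By default the index is computed over patients that belong to a
    planted group and were assigned to a cluster: the unstructured
    remainder of the population carries no ground-truth partition (its
    sidecar label is a catch-all, not a cluster), so including it would
    penalize a clustering for not lumping miscellaneous patients into one
    group.  Set ``planted_only=False`` / ``include_noise=True`` for the
    stricter variants.
    """
    truth = latent_groups.set_index("patient_id")["latent_group"]
    truth = truth.reindex(patient_labels.index)
    mask = np.ones(len(patient_labels), dtype=bool)
    if not include_noise:
        mask &= (patient_labels != NOISE).to_numpy()
    if planted_only:
        mask &= (truth != background_label).to_numpy()
    return float(adjusted_rand_score(truth[mask], patient_labels[mask]))
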