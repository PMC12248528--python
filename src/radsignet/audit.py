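"""Unsupervised batch-effect and structure audit.

Robust-scaled feature tables are projected to 2D with a neighborhood-
preserving manifold embedding (UMAP), the projection is clustered with
hierarchical density-based clustering (HDBSCAN), and every pair of clusters
is tested for enrichment in acquisition center and in tumor type with
two-sided Fisher's exact tests (Benjamini-Hochberg adjusted across pairs).
A systematic feature offset between centers shows up as center-enriched
clusters; absent such structure the p-values stay unremarkable.  The audit
only detects batch structure — it does not correct it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .feature_table import FeatureTable, standardize

__all__ = [
    "EmbeddingResult",
    "ClusterAssignment",
    "AuditReport",
    "embed_2d",
    "cluster_density",
    "cluster_enrichment",
    "audit_report",
]


class EmbeddingParameterError(ValueError):
    """Embedding cannot run with the given data size / parameters."""


@dataclass
class EmbeddingResult:
    coords: np.ndarray
    algorithm_params: dict
    seed: int
    patient_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("embedding must be n x 2")
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding coordinates must be finite")


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        observed = set(self.labels) - {-1}
        if observed and (min(observed) < 0 or max(observed) >= self.n_clusters):
            raise ValueError("cluster labels must lie in {-1, 0..n_clusters-1}")


def _looks_robust_scaled(values: np.ndarray) -> bool:
    med = np.nanmedian(values, axis=0)
    q1, q3 = np.nanpercentile(values, [25, 75], axis=0)
    iqr = q3 - q1
    varying = iqr > 0
    if not varying.any():
        return True
    return bool(np.median(np.abs(med[varying])) < 0.5
                and abs(np.median(iqr[varying]) - 1.0) < 0.5)


def embed_2d(table: FeatureTable, seed: int = 0,
             params: dict | None = None) -> EmbeddingResult:
    """Deterministic 2D manifold embedding of a robust-standardized table.

    Delegates to UMAP with its defaults unless overridden through
    ``params``; ``n_neighbors`` is clamped below the cohort size.  Warns if
    the table does not look robust-standardized (median ~ 0, IQR ~ 1).
    """
    if table.n_patients < 10:
        raise EmbeddingParameterError(
            f"embedding needs >= 10 patients to build a neighbor graph, "
            f"got {table.n_patients}; collect more samples or skip the audit")
    if not _looks_robust_scaled(table.values):
        warnings.warn("feature table does not look robust-standardized; "
                      "run standardize(table, 'robust') first", stacklevel=2)
    import umap  # deferred: heavy import

    params = dict(params or {})
    params.setdefault("n_neighbors", min(15, table.n_patients - 2))
    params["n_neighbors"] = min(params["n_neighbors"], table.n_patients - 2)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*n_jobs value.*")
        reducer = umap.UMAP(n_components=2, random_state=seed, **params)
        coords = reducer.fit_transform(table.values)
    recorded = {"algorithm": "umap", **params}
    return EmbeddingResult(coords, recorded, seed, list(table.patient_ids))


def cluster_density(embedding: EmbeddingResult, min_cluster_size: int = 5) -> ClusterAssignment:
    """Hierarchical density-based clustering of the 2D coordinates (HDBSCAN);
    points in no dense region are labeled -1 (noise)."""
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    if np.all(embedding.coords == embedding.coords[0]):
        # fully degenerate geometry: one dense point, a single cluster
        return ClusterAssignment(np.zeros(len(embedding.coords), int), 1)
    from sklearn.cluster import HDBSCAN

    labels = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(
        embedding.coords)
    labels = np.asarray(labels, dtype=int)
    n_clusters = int(labels.max()) + 1 if (labels >= 0).any() else 0
    return ClusterAssignment(labels, n_clusters)


def cluster_enrichment(assignment: ClusterAssignment, category,
                       label_type: str = "category") -> pd.DataFrame:
    """Pairwise Fisher's exact enrichment of clusters against a binary label.

    For every unordered pair of non-noise clusters, a 2x2 table (cluster
    membership x category level) is built from the members of the two
    clusters only and the two-sided Fisher exact p-value computed; raw and
    Benjamini-Hochberg-adjusted p-values are reported.  Noise points never
    enter any table.  With fewer than two clusters an empty report is
    returned with a notice.
    """
    category = np.asarray(category)
    if category.shape[0] != assignment.labels.shape[0]:
        raise ValueError("category vector must align with cluster labels")
    clusters = sorted(set(assignment.labels) - {-1})
    columns = ["label_type", "cluster_a", "cluster_b", "a_pos", "a_neg",
               "b_pos", "b_neg", "p_value", "p_adjusted"]
    if len(clusters) < 2:
        warnings.warn("fewer than two non-noise clusters; no enrichment computed",
                      stacklevel=2)
        return pd.DataFrame(columns=columns)
    levels = np.unique(category)
    positive = levels[-1]
    rows = []
    for a, b in combinations(clusters, 2):
        in_a = assignment.labels == a
        in_b = assignment.labels == b
        table = np.array([
            [int(np.sum(in_a & (category == positive))),
             int(np.sum(in_a & (category != positive)))],
            [int(np.sum(in_b & (category == positive))),
             int(np.sum(in_b & (category != positive)))],
        ])
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        rows.append({"label_type": label_type, "cluster_a": a, "cluster_b": b,
                     "a_pos": table[0, 0], "a_neg": table[0, 1],
                     "b_pos": table[1, 0], "b_neg": table[1, 1], "p_value": p})
    report = pd.DataFrame(rows)
    report["p_adjusted"] = _benjamini_hochberg(report["p_value"].to_numpy())
    return report[columns]


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


@dataclass
class AuditReport:
    embedding: EmbeddingResult
    clusters: ClusterAssignment
    enrichment: pd.DataFrame
    joint_center_tumor_p: float
    seed: int


def audit_report(table: FeatureTable, centers, labels, seed: int = 0,
                 min_cluster_size: int = 5,
                 embed_params: dict | None = None) -> AuditReport:
    """Full batch-effect audit of a raw feature table.

    Robust-scales the table, embeds it in 2D, clusters the embedding, and
    computes pairwise cluster enrichment for the acquisition center and for
    the tumor label, plus one joint center x tumor Fisher test on the whole
    cohort.  Deterministic under ``seed``.
    """
    centers = np.asarray(centers).astype(int)
    labels = np.asarray(labels).astype(int)
    if len(centers) != table.n_patients or len(labels) != table.n_patients:
        raise ValueError("centers and labels must align with the feature table")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-column warnings are expected
        scaled, _ = standardize(table, "robust")
    embedding = embed_2d(scaled, seed=seed, params=embed_params)
    clusters = cluster_density(embedding, min_cluster_size=min_cluster_size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        enrichment = pd.concat([
            cluster_enrichment(clusters, centers, "center"),
            cluster_enrichment(clusters, labels, "tumor_type"),
        ], ignore_index=True)
    joint = np.array([
        [int(np.sum((centers == 0) & (labels == 0))),
         int(np.sum((centers == 0) & (labels == 1)))],
        [int(np.sum((centers == 1) & (labels == 0))),
         int(np.sum((centers == 1) & (labels == 1)))],
    ])
    joint_p = float(stats.fisher_exact(joint, alternative="two-sided")[1])
    return AuditReport(embedding, clusters, enrichment, joint_p, seed)
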