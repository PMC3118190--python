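"""K-means clustering of 4-stage expression profiles with trend labelling.

Profiles (RPKM per stage) are clustered by Lloyd's algorithm with Euclidean
distance, K = 20 clusters and an iteration cap of 50 by default.  Cluster
centroids are then labelled increasing / decreasing / steady by a
monotonicity-and-fold rule, the programmatic stand-in for visual scoring of
cluster shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClusterConfig",
    "TrendRule",
    "ClusterResult",
    "kmeans_cluster",
    "classify_trend",
    "cluster_report",
]

TRENDS = ("increasing", "decreasing", "steady")


@dataclass(frozen=True)
class ClusterConfig:
    k: int = 20
    max_iter: int = 50
    seed: int = 0
    n_init: int = 1
    log_transform: bool = False  # cluster on log2(RPKM+1) instead of raw RPKM

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")


@dataclass(frozen=True)
class TrendRule:
    """A centroid is increasing iff it is non-decreasing stage-to-stage and
    its overall fold (last+eps)/(first+eps) reaches ``fold``; symmetrically
    for decreasing; everything else is steady."""

    fold: float = 2.0
    eps: float = 1.0
    max_violations: int = 0  # tolerated monotonicity violations

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("fold threshold must be > 1")
        if self.eps <= 0:
            raise ValueError("pseudocount eps must be > 0")


@dataclass
class ClusterResult:
    labels: pd.Series  # gene_id -> cluster id
    centroids: np.ndarray  # k x n_stages, in the clustering space
    inertia: float  # final within-cluster sum of squares
    n_iter: int
    log_transformed: bool = False
    objective_trace: list[float] = field(default_factory=list)
    stage_names: list[str] = field(default_factory=list)

    @property
    def centroids_rpkm(self) -> np.ndarray:
        """Centroids on the RPKM scale (inverse log2(x+1) if clustering was log)."""
        if self.log_transformed:
            return np.maximum(2.0**self.centroids - 1.0, 0.0)
        return self.centroids

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels.to_numpy(), minlength=self.k)

    def to_tsv(self, assignments_path: str, centroids_path: str) -> None:
        self.labels.rename("cluster").to_csv(assignments_path, sep="\t", index_label="gene_id")
        cols = self.stage_names or [f"stage{i+1}" for i in range(self.centroids.shape[1])]
        pd.DataFrame(self.centroids, columns=cols).to_csv(
            centroids_path, sep="\t", index_label="cluster"
        )


def _lloyd(X: np.ndarray, k: int, max_iter: int, rng: np.random.Generator):
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].astype(float).copy()
    labels = np.full(n, -1)
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        # empty cluster: reseed with the point farthest from its centroid
        for c in range(k):
            if not (new_labels == c).any():
                far = d2[np.arange(n), new_labels].argmax()
                centroids[c] = X[far]
                d2[:, c] = ((X - centroids[c]) ** 2).sum(axis=1)
                new_labels = d2.argmin(axis=1)
        trace.append(float(d2[np.arange(n), new_labels].sum()))
        if (new_labels == labels).all():
            labels = new_labels
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = X[labels == c].mean(axis=0)
    inertia = float(((X - centroids[labels]) ** 2).sum())
    return labels, centroids, inertia, n_iter, trace


def kmeans_cluster(profiles: pd.DataFrame, cfg: ClusterConfig | None = None) -> ClusterResult:
    """Lloyd's K-means on per-gene stage profiles (rows = genes).

    Initialization selects k distinct profiles at random under the seed;
    the within-cluster sum of squares is non-increasing across iterations
    and the best of ``n_init`` restarts is kept.
    """
    cfg = cfg or ClusterConfig()
    if len(profiles) < cfg.k:
        raise ValueError(f"need at least k={cfg.k} profiles, got {len(profiles)}")
    X = profiles.to_numpy(dtype=float)
    if cfg.log_transform:
        X = np.log2(X + 1.0)
    rng = np.random.default_rng(cfg.seed)
    best = None
    for _ in range(cfg.n_init):
        labels, centroids, inertia, n_iter, trace = _lloyd(X, cfg.k, cfg.max_iter, rng)
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia, n_iter, trace)
    labels, centroids, inertia, n_iter, trace = best
    return ClusterResult(
        labels=pd.Series(labels, index=profiles.index, name="cluster"),
        centroids=centroids,
        inertia=inertia,
        n_iter=n_iter,
        log_transformed=cfg.log_transform,
        objective_trace=trace,
        stage_names=list(profiles.columns),
    )


def classify_trend(centroid: np.ndarray, rule: TrendRule | None = None) -> str:
    """Label a centroid increasing / decreasing / steady by monotonicity + fold."""
    rule = rule or TrendRule()
    c = np.asarray(centroid, dtype=float)
    diffs = np.diff(c)
    up_ok = int((diffs < 0).sum()) <= rule.max_violations
    down_ok = int((diffs > 0).sum()) <= rule.max_violations
    fold_up = (c[-1] + rule.eps) / (c[0] + rule.eps)
    if up_ok and fold_up >= rule.fold:
        return "increasing"
    if down_ok and 1.0 / fold_up >= rule.fold:
        return "decreasing"
    return "steady"


def cluster_report(
    result: ClusterResult, rule: TrendRule | None = None
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-cluster trend labels and the gene lists grouped by trend.

    Returns a summary frame (cluster, size, trend, centroid columns) and a
    trend -> gene-id list mapping.
    """
    rule = rule or TrendRule()
    trends = [classify_trend(c, rule) for c in result.centroids_rpkm]
    stage_cols = result.stage_names or [f"stage{i+1}" for i in range(result.centroids.shape[1])]
    summary = pd.DataFrame(result.centroids, columns=stage_cols)
    summary.insert(0, "cluster", np.arange(result.k))
    summary.insert(1, "size", result.sizes)
    summary.insert(2, "trend", trends)
    by_trend: dict[str, list[str]] = {t: [] for t in TRENDS}
    for gid, c in result.labels.items():
        by_trend[trends[c]].append(gid)
    return summary, by_trend
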