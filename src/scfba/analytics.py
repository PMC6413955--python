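"""Post-processing of fluxes and transcripts: normalization, clustering,
cluster-count diagnostics and between-group contrasts.

Feature matrices are features (reactions or genes) by cells.  Each feature is
min-max rescaled to [0, 1] before clustering so high-magnitude features do
not dominate the Euclidean geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import norm
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples, silhouette_score

__all__ = [
    "FeatureMatrix",
    "ClusterReport",
    "minmax_normalize",
    "hierarchical_cluster",
    "kmeans_bootstrap",
    "elbow_and_silhouette",
    "zscore_between_clusters",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """Feature x cell matrix normalized per feature to [0, 1]."""

    values: pd.DataFrame
    feature_kind: str  # "flux" | "transcript"

    @property
    def cells(self) -> list:
        return list(self.values.columns)

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ClusterReport:
    labels: Dict[int, pd.Series]  # k -> cell labels
    sse: pd.Series  # k -> within-cluster sum of squared errors
    silhouette_avg: pd.Series  # k -> mean silhouette (k >= 2)
    silhouette_cells: Dict[int, pd.Series]  # k -> per-cell silhouette
    linkage_matrix: Optional[np.ndarray] = None


def minmax_normalize(values: pd.DataFrame, feature_kind: str = "flux") -> FeatureMatrix:
    """Rescale each feature row to [0, 1]; constant rows become all zeros."""
    arr = values.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("feature matrix contains non-finite entries")
    lo = arr.min(axis=1, keepdims=True)
    hi = arr.max(axis=1, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span > 0, (arr - lo) / np.where(span > 0, span, 1.0), 0.0)
    return FeatureMatrix(
        values=pd.DataFrame(out, index=values.index, columns=values.columns),
        feature_kind=feature_kind,
    )


def hierarchical_cluster(features: FeatureMatrix, method: str = "average") -> np.ndarray:
    """Agglomerative linkage over cells (Euclidean distance).

    Returns the scipy linkage matrix; feed it to ``scipy.cluster.hierarchy``
    for dendrograms / flat cuts.
    """
    if features.n_cells < 2:
        raise ValueError("hierarchical clustering needs at least 2 cells")
    return linkage(features.values.to_numpy().T, method=method, metric="euclidean")


def kmeans_bootstrap(
    features: FeatureMatrix, k: int, n_restarts: int = 100, seed: int = 0
) -> pd.Series:
    """Best-of-*n_restarts* k-means with random centroid initializations.

    The restart with the maximum between-cluster sum of squares is kept
    (equivalently the minimum within-cluster SSE, total being fixed).
    Deterministic for a given seed.
    """
    if not 1 <= k <= features.n_cells:
        raise ValueError(f"k={k} outside 1..{features.n_cells}")
    X = features.values.to_numpy().T
    rng = np.random.default_rng(seed)
    best_labels, best_sse = None, np.inf
    for _ in range(n_restarts):
        km = KMeans(
            n_clusters=k,
            init="random",
            n_init=1,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(X)
        if km.inertia_ < best_sse:
            best_sse = km.inertia_
            best_labels = km.labels_
    return pd.Series(best_labels, index=features.cells, name=f"k{k}")


def elbow_and_silhouette(
    features: FeatureMatrix,
    k_range: Sequence[int] = range(1, 21),
    n_restarts: int = 100,
    seed: int = 0,
    linkage_method: str = "average",
) -> ClusterReport:
    """SSE (elbow) curve and silhouette coefficients over a range of k."""
    X = features.values.to_numpy().T
    labels: Dict[int, pd.Series] = {}
    sse: Dict[int, float] = {}
    sil_avg: Dict[int, float] = {}
    sil_cells: Dict[int, pd.Series] = {}
    for k in k_range:
        if k > features.n_cells:
            continue
        if k == 1:
            lab = pd.Series(0, index=features.cells, name="k1")
            centroid = X.mean(axis=0)
            sse[1] = float(((X - centroid) ** 2).sum())
        else:
            lab = kmeans_bootstrap(features, k, n_restarts=n_restarts, seed=seed + k)
            sse[k] = _sse(X, lab.to_numpy())
            if len(np.unique(lab)) > 1:
                sil_avg[k] = float(silhouette_score(X, lab.to_numpy(), metric="euclidean"))
                sil_cells[k] = pd.Series(
                    silhouette_samples(X, lab.to_numpy(), metric="euclidean"),
                    index=features.cells,
                )
        labels[k] = lab
    link = hierarchical_cluster(features, method=linkage_method) if features.n_cells >= 2 else None
    return ClusterReport(
        labels=labels,
        sse=pd.Series(sse).sort_index(),
        silhouette_avg=pd.Series(sil_avg).sort_index(),
        silhouette_cells=sil_cells,
        linkage_matrix=link,
    )


def _sse(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        members = X[labels == lab]
        total += float(((members - members.mean(axis=0)) ** 2).sum())
    return total


def zscore_between_clusters(
    features: FeatureMatrix,
    labels: pd.Series,
    confidence: float = 0.99,
) -> pd.DataFrame:
    """Two-sample (unequal-variance) z contrast of every feature between two groups.

    ``z = (mean1 - mean2) / sqrt(s1^2/n1 + s2^2/n2)``; features whose |z|
    exceeds the two-sided critical value at *confidence* are flagged.
    """
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"labels must define exactly two groups, got {len(groups)}")
    cells1 = labels.index[labels == groups[0]]
    cells2 = labels.index[labels == groups[1]]
    if len(cells1) < 2 or len(cells2) < 2:
        raise ValueError("each group needs at least 2 cells (variance undefined)")
    X1 = features.values[cells1].to_numpy()
    X2 = features.values[cells2].to_numpy()
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    v1 = X1.var(axis=1, ddof=1)
    v2 = X2.var(axis=1, ddof=1)
    denom = np.sqrt(v1 / X1.shape[1] + v2 / X2.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(denom > 0, (m1 - m2) / np.where(denom > 0, denom, 1.0), 0.0)
    critical = float(norm.ppf(1 - (1 - confidence) / 2))
    return pd.DataFrame(
        {"z": z, "significant": np.abs(z) > critical},
        index=features.values.index,
    )
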