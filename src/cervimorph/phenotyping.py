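"""Unsupervised phenotyping of alignment parameters.

Pipeline: z-score standardization (sample SD, ddof=1) → optional PCA →
k-means over a scanned range of k with four validity criteria (within-
cluster sum of squares for the elbow method, mean silhouette,
Calinski–Harabasz, Davies–Bouldin) → cluster naming by the alignment
profile each cluster exhibits.

Clustering operates on the standardized 4-parameter matrix by default;
``feature_space="pca_scores"`` clusters PCA-transformed features instead.
Both readings are exposed because the two differ only by an orthogonal
rotation when all components are retained, but not when components are
truncated.

Phenotype names follow the alignment profile: the cluster with the highest
mean lordosis is the biomechanically balanced "normal" type; among the
rest, the one with the longest mean vertical length is the elongated
"long-neck" type; the remaining cluster, with low lordosis (kyphotic
tendency) and moderate anterior displacement, is the "forward-head" type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (
    calinski_harabasz_score,
    silhouette_score,
)

from .stats import ClusterSummary

__all__ = [
    "ScalerParams",
    "ClusterModel",
    "KScanResult",
    "PcaResult",
    "standardize",
    "pca_fit_transform",
    "kmeans_fit",
    "wcss",
    "silhouette_mean",
    "calinski_harabasz",
    "davies_bouldin",
    "scan_k",
    "select_k",
    "label_clusters",
    "profile_zscores",
]

PHENOTYPE_NORMAL = "normal"
PHENOTYPE_LONG_NECK = "long-neck"
PHENOTYPE_FORWARD_HEAD = "forward-head"


@dataclass(frozen=True)
class ScalerParams:
    """Per-column mean and sample SD used for z-scoring."""

    columns: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.sd + self.mean


@dataclass
class ClusterModel:
    """Fitted k-means state."""

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    seed: int
    feature_space: Literal["standardized", "pca_scores"] = "standardized"
    inertia: float = float("nan")


@dataclass
class KScanResult:
    """Per-k validity metrics over a scanned range of cluster counts."""

    ks: tuple[int, ...]
    wcss: tuple[float, ...]
    silhouette: tuple[float, ...]
    calinski_harabasz: tuple[float, ...]
    davies_bouldin: tuple[float, ...]
    models: dict[int, ClusterModel] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.ks,
                "wcss": self.wcss,
                "silhouette": self.silhouette,
                "calinski_harabasz": self.calinski_harabasz,
                "davies_bouldin": self.davies_bouldin,
            }
        )


@dataclass
class PcaResult:
    """Scores, loadings and explained-variance ratios of a PCA fit."""

    scores: np.ndarray
    loadings: np.ndarray  # rows = components, columns = input features
    explained_variance_ratio: np.ndarray

    @property
    def cumulative_ratio(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def standardize(
    X: pd.DataFrame | np.ndarray, columns: Sequence[str] | None = None
) -> tuple[np.ndarray, ScalerParams]:
    """Z-score each column using the sample SD (ddof=1).

    Raises for constant columns, naming the offending parameter.
    """
    if isinstance(X, pd.DataFrame):
        names = tuple(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        names = tuple(columns) if columns else tuple(f"x{i}" for i in range(arr.shape[1]))
    if arr.shape[0] < 2:
        raise ValueError("standardization needs at least 2 rows")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    bad = [names[i] for i in np.nonzero(sd <= 1e-12)[0]]
    if bad:
        raise ValueError(f"constant column(s), cannot z-score: {', '.join(bad)}")
    scaler = ScalerParams(columns=names, mean=mean, sd=sd)
    return scaler.transform(arr), scaler


def pca_fit_transform(
    Z: np.ndarray,
    n_components: int | None = None,
    variance_threshold: float | None = None,
) -> PcaResult:
    """PCA of a standardized matrix.

    With ``variance_threshold`` set, retains the smallest number of leading
    components whose cumulative explained-variance ratio reaches it.
    """
    Z = np.asarray(Z, dtype=float)
    max_comp = min(Z.shape)
    if n_components is not None and n_components > Z.shape[1]:
        raise ValueError("n_components exceeds the number of features")
    pca = PCA(n_components=max_comp, svd_solver="full")
    scores = pca.fit_transform(Z)
    ratios = pca.explained_variance_ratio_
    keep = max_comp
    if variance_threshold is not None:
        keep = int(np.searchsorted(np.cumsum(ratios), variance_threshold) + 1)
        keep = min(keep, max_comp)
    if n_components is not None:
        keep = n_components
    return PcaResult(
        scores=scores[:, :keep],
        loadings=pca.components_[:keep],
        explained_variance_ratio=ratios[:keep],
    )


# ---------------------------------------------------------------------------
# k-means and validity indices
# ---------------------------------------------------------------------------


def kmeans_fit(
    F: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    feature_space: Literal["standardized", "pca_scores"] = "standardized",
    init: np.ndarray | str = "k-means++",
) -> ClusterModel:
    """Best-of-``n_init`` Lloyd k-means with k-means++ seeding.

    Deterministic given ``seed``; converges on centroid shift < 1e-6 or 300
    iterations, mirroring common defaults.
    """
    F = np.asarray(F, dtype=float)
    if not 1 <= k <= F.shape[0]:
        raise ValueError(f"k={k} must lie in [1, n={F.shape[0]}]")
    if isinstance(init, np.ndarray):
        n_init = 1
    km = KMeans(
        n_clusters=k,
        init=init,
        n_init=n_init,
        max_iter=300,
        tol=1e-6,
        random_state=seed,
        algorithm="lloyd",
    )
    labels = km.fit_predict(F)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        labels=labels,
        seed=seed,
        feature_space=feature_space,
        inertia=float(km.inertia_),
    )


def wcss(model: ClusterModel, F: np.ndarray) -> float:
    """Within-cluster sum of squared distances to assigned centroids."""
    F = np.asarray(F, dtype=float)
    diffs = F - model.centroids[model.labels]
    return float((diffs**2).sum())


def _check_partition(labels: np.ndarray, min_k: int = 2) -> int:
    k = np.unique(labels).size
    if k < min_k:
        raise ValueError(f"metric undefined for fewer than {min_k} clusters")
    return k


def silhouette_mean(F: np.ndarray, labels: Sequence[int]) -> float:
    """Mean silhouette coefficient (b - a) / max(a, b); singletons score 0."""
    F = np.asarray(F, dtype=float)
    labels = np.asarray(labels)
    _check_partition(labels)
    return float(silhouette_score(F, labels))


def calinski_harabasz(F: np.ndarray, labels: Sequence[int]) -> float:
    """Between/within dispersion ratio scaled by (n - k) / (k - 1)."""
    F = np.asarray(F, dtype=float)
    labels = np.asarray(labels)
    _check_partition(labels)
    return float(calinski_harabasz_score(F, labels))


def davies_bouldin(F: np.ndarray, labels: Sequence[int]) -> float:
    """Mean over clusters of the worst (s_i + s_j) / d_ij similarity ratio.

    s_i is the mean distance of cluster i's members to its centroid, d_ij
    the distance between centroids. Coincident centroids of distinct
    clusters make the index infinite; this is flagged with a warning.
    """
    F = np.asarray(F, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = _check_partition(labels)
    centroids = np.stack([F[labels == c].mean(axis=0) for c in uniq])
    spreads = np.array(
        [np.linalg.norm(F[labels == c] - centroids[i], axis=1).mean() for i, c in enumerate(uniq)]
    )
    worst = np.zeros(k)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            d = np.linalg.norm(centroids[i] - centroids[j])
            if d == 0.0:
                warnings.warn("coincident cluster centroids: Davies-Bouldin is infinite",
                              stacklevel=2)
                return float("inf")
            worst[i] = max(worst[i], (spreads[i] + spreads[j]) / d)
    return float(worst.mean())


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


def scan_k(
    F: np.ndarray,
    k_range: Iterable[int] = range(2, 9),
    seed: int = 0,
    n_init: int = 10,
    feature_space: Literal["standardized", "pca_scores"] = "standardized",
) -> KScanResult:
    """Fit k-means for each k and record all four validity metrics.

    For each k beyond the first, a warm-started replicate (previous
    centroids plus the point farthest from them) competes with the fresh
    best-of-``n_init`` fit; the lower-WCSS solution wins, which guarantees a
    non-increasing WCSS curve for the elbow method.
    """
    F = np.asarray(F, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    rows: dict[str, list[float]] = {m: [] for m in ("wcss", "sil", "ch", "db")}
    models: dict[int, ClusterModel] = {}
    prev: ClusterModel | None = None
    for k in ks:
        model = kmeans_fit(F, k, seed=seed, n_init=n_init, feature_space=feature_space)
        if prev is not None and prev.k == k - 1:
            dists = np.linalg.norm(F[:, None, :] - prev.centroids[None], axis=2).min(axis=1)
            warm_init = np.vstack([prev.centroids, F[int(np.argmax(dists))]])
            warm = kmeans_fit(F, k, seed=seed, feature_space=feature_space, init=warm_init)
            if wcss(warm, F) < wcss(model, F):
                model = warm
        models[k] = model
        rows["wcss"].append(wcss(model, F))
        if k >= 2 and np.unique(model.labels).size >= 2:
            rows["sil"].append(silhouette_mean(F, model.labels))
            rows["ch"].append(calinski_harabasz(F, model.labels))
            rows["db"].append(davies_bouldin(F, model.labels))
        else:
            rows["sil"].append(float("nan"))
            rows["ch"].append(float("nan"))
            rows["db"].append(float("nan"))
        prev = model
    return KScanResult(
        ks=tuple(ks),
        wcss=tuple(rows["wcss"]),
        silhouette=tuple(rows["sil"]),
        calinski_harabasz=tuple(rows["ch"]),
        davies_bouldin=tuple(rows["db"]),
        models=models,
    )


def select_k(
    scan: KScanResult,
    strategy: Literal["silhouette_max", "elbow_knee", "manual"] = "silhouette_max",
    k: int | None = None,
) -> int:
    """Choose the number of clusters from a scan.

    ``silhouette_max`` takes the k with the highest mean silhouette.
    ``elbow_knee`` takes the k whose WCSS point is farthest (perpendicular
    distance) from the chord joining the first and last points of the WCSS
    curve — a standard formalisation of the visual elbow. ``manual``
    requires an explicit k inside the scanned range.
    """
    if not scan.ks:
        raise ValueError("empty scan")
    if strategy == "manual":
        if k is None or k not in scan.ks:
            raise ValueError("manual selection needs a k within the scanned range")
        return k
    if strategy == "silhouette_max":
        sil = np.asarray(scan.silhouette)
        if np.all(np.isnan(sil)):
            raise ValueError("no silhouette values in scan")
        return scan.ks[int(np.nanargmax(sil))]
    if strategy == "elbow_knee":
        ks = np.asarray(scan.ks, dtype=float)
        w = np.asarray(scan.wcss, dtype=float)
        if ks.size < 3:
            return scan.ks[0]
        p0 = np.array([ks[0], w[0]])
        p1 = np.array([ks[-1], w[-1]])
        chord = p1 - p0
        chord_len = np.linalg.norm(chord)
        pts = np.stack([ks, w], axis=1) - p0
        dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / chord_len
        return scan.ks[int(np.argmax(dist))]
    raise ValueError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# Phenotype naming and profiles
# ---------------------------------------------------------------------------


def label_clusters(summary: ClusterSummary) -> dict[int, str]:
    """Map cluster ids to phenotype names for a three-cluster solution.

    Highest mean lordosis → "normal"; of the rest, highest mean vertical
    length → "long-neck"; the remaining cluster → "forward-head". For k != 3
    the mapping falls back to neutral "cluster_i" names.
    """
    clusters = list(summary.clusters)
    if len(clusters) != 3:
        return {c: f"cluster_{c}" for c in clusters}
    normal = max(clusters, key=lambda c: summary.mean(c, "lordosis_deg"))
    rest = [c for c in clusters if c != normal]
    long_neck = max(rest, key=lambda c: summary.mean(c, "vertical_length"))
    forward = next(c for c in rest if c != long_neck)
    return {normal: PHENOTYPE_NORMAL, long_neck: PHENOTYPE_LONG_NECK,
            forward: PHENOTYPE_FORWARD_HEAD}


def profile_zscores(summary: ClusterSummary, scaler: ScalerParams) -> pd.DataFrame:
    """Standardized per-cluster mean profiles: (cluster mean − cohort mean)/SD.

    Rows are clusters, columns parameters — the data behind a standardized
    feature-profile plot.
    """
    cols = scaler.columns
    data = np.stack(
        [
            (np.array([summary.mean(c, p) for p in cols]) - scaler.mean) / scaler.sd
            for c in summary.clusters
        ]
    )
    return pd.DataFrame(data, index=list(summary.clusters), columns=list(cols))
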