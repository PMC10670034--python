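"""Explanation-weighted clustering: from weighted images to scored clusters.

An explanation-weighted image is the Hadamard product I_Y = I ⊙ Y⁺ of an image
with the non-negative part of its explanation, so only the pixels the
classifier relied on survive. Those images are embedded with the classifier's
penultimate-layer features, reduced by SVD, and clustered with K-means; the
number of clusters is chosen as the silhouette-coefficient maximum over a
range of K. Cluster quality is scored by the plain Rand index against a
ground-truth subtype labelling (when available), the silhouette coefficient,
and the Davies-Bouldin index.

The numerical workhorses (k-means++/Lloyd, PCA-style SVD, the three metrics)
are scikit-learn; this module fixes the conventions — tie-breaks toward
smaller K, nearest-centroid assignment of unseen images, deterministic
component signs — and the result containers.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, rand_score, silhouette_score

from .errors import (DegenerateDataError, DimensionError, MetricError,
                     ParameterError, ReductionError)
from .occlusion import ImportanceMap


def weight_image(image: np.ndarray, explanation: ImportanceMap | np.ndarray) -> np.ndarray:
    """I_Y = I ⊙ Y⁺: broadcast the clamped-to-non-negative explanation across
    the three channels. Monotone in the explanation; pixels with Y⁺ = 0 are
    exactly zero."""
    values = explanation.values if isinstance(explanation, ImportanceMap) else explanation
    image = np.asarray(image, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if image.shape[:2] != values.shape:
        raise DimensionError(
            f"image {image.shape[:2]} and explanation {values.shape} disagree")
    y_pos = np.clip(values, 0.0, None)
    return image * y_pos[..., None]


@dataclasses.dataclass
class FeatureMatrix:
    """SVD-reduced feature rows plus the fitted projection, so held-out
    feature vectors can be mapped into the same space."""

    values: np.ndarray
    row_ids: list
    explained_variance_ratio: np.ndarray
    _pca: PCA

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def transform(self, features: np.ndarray) -> np.ndarray:
        """Project raw penultimate-layer vectors with the fitted reduction."""
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        return self._pca.transform(features)


def reduce_features(
    features: np.ndarray,
    target_dim: int | None = None,
    variance_fraction: float = 0.9,
    cap: int = 32,
    row_ids: Sequence | None = None,
) -> FeatureMatrix:
    """Project column-centered features onto their top singular directions.

    With ``target_dim=None`` the dimension is the smallest capturing
    ``variance_fraction`` of the variance, capped at
    min(cap, n_rows - 1, n_features). Deterministic: full SVD with the
    standard sign convention (largest-magnitude loading positive).
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ReductionError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(x)):
        raise ReductionError("features contain non-finite entries")
    max_dim = min(x.shape[0] - 1, x.shape[1])
    if target_dim is not None:
        if not 1 <= target_dim <= max_dim:
            raise ReductionError(
                f"target_dim must be in [1, {max_dim}] for shape {x.shape}")
        k = target_dim
    else:
        probe = PCA(svd_solver="full").fit(x)
        cum = np.cumsum(probe.explained_variance_ratio_)
        k = int(np.searchsorted(cum, variance_fraction) + 1)
        k = min(k, cap, max_dim)
    pca = PCA(n_components=k, svd_solver="full").fit(x)
    values = pca.transform(x)
    ids = list(row_ids) if row_ids is not None else list(range(x.shape[0]))
    return FeatureMatrix(values=values, row_ids=ids,
                         explained_variance_ratio=pca.explained_variance_ratio_,
                         _pca=pca)


@dataclasses.dataclass
class ClusterResult:
    """K-means outcome with the quality-metric triple."""

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    silhouette: float
    davies_bouldin: float
    sizes: list[int]
    rand_vs_truth: float | None = None

    def to_dict(self) -> dict:
        return dict(k=self.k, labels=self.labels.tolist(),
                    centroids=self.centroids.tolist(), inertia=self.inertia,
                    silhouette=self.silhouette, davies_bouldin=self.davies_bouldin,
                    sizes=self.sizes, rand_vs_truth=self.rand_vs_truth)


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, FeatureMatrix):
        return x.values
    return np.asarray(x, dtype=np.float64)


def rand_index(labels_a, labels_b, adjusted: bool = False) -> float:
    """Fraction of point pairs on which two labelings agree (together/apart);
    in [0, 1] and invariant to relabeling either side. ``adjusted=True`` gives
    the chance-corrected form."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise DimensionError("labelings must have equal length")
    if a.size < 2:
        raise DimensionError("need at least 2 points")
    return float(adjusted_rand_score(a, b) if adjusted else rand_score(a, b))


def silhouette(x, labels) -> float:
    """Mean silhouette coefficient (b - a)/max(a, b) over points; in [-1, 1].
    Points in singleton clusters score 0.

    Distances are precomputed with :func:`scipy.spatial.distance.cdist`; the
    quadratic-expansion Euclidean shortcut loses ~1e-8 of precision, which
    matters when scores are compared across near-tied clusterings.
    """
    x = _as_matrix(x)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise MetricError("silhouette requires at least 2 clusters")
    return float(silhouette_score(cdist(x, x), labels, metric="precomputed"))


def davies_bouldin(x, labels) -> float:
    """Mean over clusters of the worst (s_i + s_j)/d_ij ratio, with s the mean
    distance of a cluster's points to its centroid and d the centroid
    distance; >= 0, lower is better. Pairs with coincident centroids and zero
    scatter contribute 0."""
    x = _as_matrix(x)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise MetricError("Davies-Bouldin requires at least 2 clusters")
    centroids = np.stack([x[labels == k].mean(axis=0) for k in uniq])
    scatter = np.array([
        cdist(x[labels == k], centroids[i][None]).mean()
        for i, k in enumerate(uniq)])
    gaps = cdist(centroids, centroids)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = (scatter[:, None] + scatter[None, :]) / gaps
    ratios[~np.isfinite(ratios)] = 0.0
    np.fill_diagonal(ratios, 0.0)
    return float(ratios.max(axis=1).mean())


def kmeans(
    x,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    truth=None,
) -> ClusterResult:
    """K-means++ initialized Lloyd clustering, best of ``n_restarts`` by
    inertia. When ``truth`` labels are given, the plain Rand index against
    them is recorded."""
    mat = _as_matrix(x)
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > mat.shape[0]:
        raise DegenerateDataError(f"k={k} exceeds {mat.shape[0]} rows")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                algorithm="lloyd", random_state=seed).fit(mat)
    labels = km.labels_.astype(int)
    uniq = np.unique(labels)
    scorable = uniq.size > 1 and k < mat.shape[0]
    sil = silhouette(mat, labels) if scorable else 0.0
    db = davies_bouldin(mat, labels) if scorable else 0.0
    rand = rand_index(truth, labels) if truth is not None else None
    return ClusterResult(
        k=k, labels=labels, centroids=km.cluster_centers_,
        inertia=float(km.inertia_), silhouette=sil, davies_bouldin=db,
        sizes=np.bincount(labels, minlength=k).tolist(), rand_vs_truth=rand)


@dataclasses.dataclass
class KSelection:
    """Outcome of silhouette-driven model selection over a K range."""

    k_star: int
    table: pd.DataFrame
    results: dict[int, ClusterResult]

    @property
    def best(self) -> ClusterResult:
        return self.results[self.k_star]

    @property
    def weak_structure(self) -> bool:
        """True when no K achieves silhouette >= 0.25 (no convincing clusters)."""
        return bool(self.table["silhouette"].max() < 0.25)


def select_k(
    x,
    k_min: int = 2,
    k_max: int = 6,
    seed: int = 0,
    n_restarts: int = 10,
    truth=None,
) -> KSelection:
    """Cluster repeatedly for K in [k_min, k_max] and pick the K with the
    highest silhouette coefficient, ties broken toward smaller K."""
    mat = _as_matrix(x)
    if k_min < 2 or k_max < k_min:
        raise ParameterError("need 2 <= k_min <= k_max")
    if k_max > mat.shape[0] - 1:
        raise ParameterError(
            f"k_max={k_max} too large for {mat.shape[0]} rows")
    results: dict[int, ClusterResult] = {}
    rows = []
    for k in range(k_min, k_max + 1):
        res = kmeans(mat, k, seed=seed, n_restarts=n_restarts, truth=truth)
        results[k] = res
        rows.append(dict(k=k, silhouette=res.silhouette,
                         davies_bouldin=res.davies_bouldin, inertia=res.inertia))
    table = pd.DataFrame(rows)
    k_star = int(table.loc[table["silhouette"].idxmax(), "k"])  # idxmax -> first max
    return KSelection(k_star=k_star, table=table, results=results)


def assign_unseen(result: ClusterResult, features: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels for held-out (already reduced) feature rows;
    equidistant points go to the lowest-index centroid."""
    feats = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if feats.shape[1] != result.centroids.shape[1]:
        raise DimensionError(
            f"feature dim {feats.shape[1]} != centroid dim "
            f"{result.centroids.shape[1]}")
    d2 = ((feats[:, None, :] - result.centroids[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)
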