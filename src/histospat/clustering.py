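"""Cohort stratification: K-means over per-patient PCF curves, silhouette
K selection, PCA projection, spatial-group labeling, and 2×2 association
tests.

Patients are clustered on their raw mean-PCF vectors (all radii share units
and scale, so no standardization is applied).  The number of clusters is
chosen by maximizing the average silhouette width over K = 2..K_max; the
silhouette is undefined for K = 1, which is recorded as NaN.  When the
optimum is two clusters, the cluster whose centroid stays closest to the
CSR reference g ≡ 1 at radii beyond 8 µm is labeled spatial Group 1 (the
"more random" group); the other becomes Group 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusteringResult",
    "ContingencyResult",
    "kmeans_cluster",
    "select_k",
    "pca_2d",
    "label_groups",
    "contingency_test",
]


@dataclass
class ClusteringResult:
    assignments: np.ndarray
    silhouette_by_k: dict[int, float]
    optimal_k: int
    pca_coords: np.ndarray
    explained_variance: np.ndarray
    group_labels: np.ndarray | None = None  # 1/2 per patient when optimal_k == 2


@dataclass
class ContingencyResult:
    table: np.ndarray
    method: str
    statistic: float
    p_value: float


def kmeans_cluster(matrix: np.ndarray, k: int, n_restarts: int = 25, seed: int | None = 0):
    """Best-of-`n_restarts` Lloyd K-means; returns (labels, within-cluster SS)."""
    matrix = np.asarray(matrix, dtype=float)
    if not 1 <= k <= len(matrix):
        raise ValueError(f"k must be in [1, n_rows], got {k} for {len(matrix)} rows")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(matrix)
    return labels, float(km.inertia_)


def select_k(
    matrix: np.ndarray,
    k_max: int = 10,
    n_restarts: int = 25,
    seed: int | None = 0,
) -> ClusteringResult:
    """Scan K = 2..k_max, pick the K maximizing average silhouette width.

    K = 1 has no silhouette and is recorded as NaN; ties break toward the
    smaller K.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = len(matrix)
    if n < 3:
        raise ValueError("need at least 3 rows to select K")
    sil: dict[int, float] = {1: float("nan")}
    labels_by_k = {}
    for k in range(2, min(k_max, n - 1) + 1):
        labels, _ = kmeans_cluster(matrix, k, n_restarts, seed)
        labels_by_k[k] = labels
        sil[k] = float(silhouette_score(matrix, labels)) if len(set(labels)) > 1 else float("nan")
    best_k = max(
        (k for k in sil if np.isfinite(sil[k])),
        key=lambda k: (sil[k], -k),
    )
    coords, ev = pca_2d(matrix)
    res = ClusteringResult(
        assignments=labels_by_k[best_k],
        silhouette_by_k=sil,
        optimal_k=best_k,
        pca_coords=coords,
        explained_variance=ev,
    )
    return res


def pca_2d(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project rows on the top-2 principal directions of the centered matrix.

    Sign convention: the largest-magnitude loading of each component is made
    positive.  Returns (coords (n, 2), explained-variance fractions (2,)).
    """
    X = np.asarray(matrix, dtype=float)
    if len(X) < 2:
        raise ValueError("PCA needs at least 2 rows")
    Xc = X - X.mean(axis=0)
    total = (Xc**2).sum()
    if total == 0:
        import warnings

        warnings.warn("constant matrix: PCA coordinates are all zero")
        return np.zeros((len(X), 2)), np.zeros(2)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(2, len(s))
    coords = np.zeros((len(X), 2))
    ev = np.zeros(2)
    for j in range(k):
        v = Vt[j]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, j] = Xc @ v
        ev[j] = s[j] ** 2 / total
    return coords, ev


def label_groups(
    result: ClusteringResult, matrix: np.ndarray, radii: np.ndarray, r_threshold: float = 8.0
) -> np.ndarray | None:
    """Assign spatial Group 1/2 labels when the optimal K is two.

    The cluster whose centroid has the smaller mean |g − 1| over radii
    > r_threshold (i.e. closer to spatial randomness) is Group 1.  Exact
    ties go to the lower cluster id.  Returns None (with a notice) when
    optimal K ≠ 2.
    """
    if result.optimal_k != 2:
        import warnings

        warnings.warn(f"optimal K is {result.optimal_k}, not 2: group labeling skipped")
        return None
    matrix = np.asarray(matrix, dtype=float)
    radii = np.asarray(radii, dtype=float)
    sel = radii > r_threshold
    dev = np.empty(2)
    for c in (0, 1):
        centroid = matrix[result.assignments == c].mean(axis=0)
        dev[c] = np.abs(centroid[sel] - 1.0).mean()
    group1_cluster = int(np.argmin(dev))  # argmin takes the lower id on ties
    groups = np.where(result.assignments == group1_cluster, 1, 2)
    result.group_labels = groups
    return groups


def contingency_test(table, method: str = "chi2") -> ContingencyResult:
    """Association test on a 2×2 count table.

    chi2: Pearson chi-square without continuity correction, df = 1.
    fisher: two-sided exact test by hypergeometric enumeration.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("table must be 2x2 non-negative integer counts")
        t = t.astype(int)
    if method == "chi2":
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            raise ValueError("chi-square test is degenerate with a zero margin")
        stat, p, _, _ = stats.chi2_contingency(t, correction=False)
        return ContingencyResult(table=t, method="chi2", statistic=float(stat), p_value=float(p))
    if method == "fisher":
        stat, p = stats.fisher_exact(t, alternative="two-sided")
        return ContingencyResult(table=t, method="fisher", statistic=float(stat), p_value=float(p))
    raise ValueError(f"unknown method {method!r}")
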