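"""K-Means segmentation of pixel spectra and comparison against NMF.

Lloyd iterations with seeded k-means++ initialization, run on exactly the
same (unnormalized) pixel matrix the factorization sees.  The inertia trace
is recorded so monotonicity is checkable.  `compare_segmentations` reports
Jaccard overlaps of the hard cluster masks against ground-truth region masks
and against Otsu-binarized NMF component images — keeping the hard-label vs
soft-component distinction explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from skimage.filters import threshold_otsu
from sklearn.cluster import kmeans_plusplus

from .datacube import PixelMatrix
from .factorization import NMFResult

__all__ = ["KMeansResult", "kmeans_segment", "compare_segmentations", "jaccard"]


@dataclass(frozen=True)
class KMeansResult:
    labels: np.ndarray            # (pixels,) cluster index in 0..k-1
    centroids: np.ndarray         # (k, channels) mean spectra
    inertia: float
    inertia_trace: np.ndarray     # per Lloyd iteration of the winning restart
    seed: int


def _row_norms_sq(V) -> np.ndarray:
    if sp.issparse(V):
        return np.asarray(V.multiply(V).sum(axis=1)).ravel()
    return (V ** 2).sum(axis=1)


def _lloyd(V, k: int, init: np.ndarray, max_iter: int, x2: np.ndarray):
    centroids = init.copy()
    labels = np.full(V.shape[0], -1)
    trace = []
    for _ in range(max_iter):
        c2 = (centroids ** 2).sum(axis=1)
        # ||x - c||^2 = ||x||^2 - 2 x.c + ||c||^2
        dots = V @ centroids.T
        if sp.issparse(dots):
            dots = np.asarray(dots.todense())
        d2 = x2[:, None] - 2 * dots + c2[None, :]
        new_labels = np.argmin(d2, axis=1)
        inertia = float(np.maximum(d2[np.arange(len(new_labels)), new_labels], 0.0).sum())
        trace.append(inertia)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = labels == j
            if members.any():
                mean = V[members].mean(axis=0)
                centroids[j] = np.asarray(mean).ravel()
            # empty cluster: keep the old centroid
    return labels, centroids, trace


def kmeans_segment(
    V: PixelMatrix | sp.spmatrix | np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> KMeansResult:
    """Segment pixel spectra into k clusters (best of ``n_init`` restarts)."""
    if isinstance(V, PixelMatrix):
        V = V.V
    if sp.issparse(V):
        V = V.tocsr()
    else:
        V = np.asarray(V, dtype=float)
    n = V.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available pixels")
    x2 = _row_norms_sq(V)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        init, _idx = kmeans_plusplus(V, n_clusters=k,
                                     random_state=int(rng.integers(2**31 - 1)))
        init = np.asarray(init.todense()) if sp.issparse(init) else np.asarray(init)
        labels, centroids, trace = _lloyd(V, k, init, max_iter, x2)
        if best is None or trace[-1] < best[2][-1]:
            best = (labels, centroids, trace)
    labels, centroids, trace = best
    if len(np.unique(labels)) < k:
        raise ValueError(f"only {len(np.unique(labels))} distinct clusters formed; "
                         f"fewer than k={k} distinct pixel spectra?")
    return KMeansResult(labels=labels, centroids=centroids, inertia=float(trace[-1]),
                        inertia_trace=np.asarray(trace), seed=seed)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks."""
    a = np.asarray(a, dtype=bool).ravel()
    b = np.asarray(b, dtype=bool).ravel()
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 0.0


def compare_segmentations(
    kmeans: KMeansResult,
    nmf: NMFResult,
    masks: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Jaccard overlap of each cluster with region masks and NMF components.

    NMF component images (soft weights) are binarized with an Otsu threshold
    before comparison; cluster labels are hard already.  Rows: clusters;
    columns: ``mask:<name>`` and ``nmf:<j>`` Jaccard scores.
    """
    k = kmeans.centroids.shape[0]
    component_masks = {}
    for j in range(nmf.k):
        w = nmf.W[:, j]
        thr = threshold_otsu(w) if np.ptp(w) > 0 else 0.0
        component_masks[f"nmf:{j}"] = w > thr
    rows = []
    for c in range(k):
        cluster_mask = kmeans.labels == c
        row = {"cluster": c, "n_pixels": int(cluster_mask.sum())}
        for name, m in masks.items():
            row[f"mask:{name}"] = jaccard(cluster_mask, m)
        for name, m in component_masks.items():
            row[name] = jaccard(cluster_mask, m)
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")
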