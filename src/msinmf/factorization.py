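"""Alternating-least-squares non-negative matrix factorization.

Minimizes D = 1/2 ||V - W H||_F^2 by alternating exact least-squares solves
with negative entries clamped to zero:

    W = V H^T (H H^T)^#     then clamp,
    H = (W^T W)^# W^T V     then clamp,

where # is the Moore-Penrose pseudoinverse.  Columns of W are the component
images (after reshaping to the pixel grid) and rows of H the component
spectra.  V may be a scipy sparse matrix; W H is never materialized densely.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .datacube import PixelMatrix

log = logging.getLogger(__name__)

__all__ = ["NMFResult", "NormalizedComponents", "nmf_als", "normalize_component_set",
           "component_assignment"]


@dataclass(frozen=True)
class NMFResult:
    W: np.ndarray                 # (pixels, k) component images, flattened
    H: np.ndarray                 # (k, channels) component spectra
    k: int
    objective_trace: np.ndarray   # D per iteration
    iterations: int
    converged: bool
    seed: int

    @property
    def final_objective(self) -> float:
        return float(self.objective_trace[-1])


@dataclass(frozen=True)
class NormalizedComponents:
    """Display-ready components: [0,1] images, spectra in % of the set base peak."""

    images: tuple[np.ndarray, ...]      # each rows x cols in [0, 1]
    spectra: np.ndarray                 # (k, channels), max over set == 100.0


def _pinv(A: np.ndarray, rcond: float = 1e-12) -> np.ndarray:
    """SVD pseudoinverse with singular values below rcond*sigma_max zeroed."""
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    cutoff = rcond * (s[0] if s.size else 0.0)
    inv = np.where(s > cutoff, 1.0 / np.where(s > cutoff, s, 1.0), 0.0)
    return (Vt.T * inv) @ U.T


def _objective(V, W: np.ndarray, H: np.ndarray, normV2: float) -> float:
    # ||V - WH||^2 = ||V||^2 - 2 <V, WH> + ||WH||^2 without forming WH
    cross = float(np.sum((V @ H.T) * W))
    wh2 = float(np.sum((W.T @ W) * (H @ H.T)))
    return 0.5 * max(normV2 - 2.0 * cross + wh2, 0.0)


def nmf_als(
    V: PixelMatrix | sp.spmatrix | np.ndarray,
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> NMFResult:
    """Factor a non-negative pixel matrix into k components.

    H is initialized i.i.d. uniform on [0.1, 1] from the seeded generator.
    Iteration stops when the relative objective change drops below ``tol``
    or after ``max_iter`` iterations.  A component whose H row (or W column)
    dies to all zeros is re-seeded once from the generator, then left alone.
    """
    if isinstance(V, PixelMatrix):
        V = V.V
    if sp.issparse(V):
        V = V.tocsr()
        if V.nnz and V.data.min() < 0:
            raise ValueError("V must be elementwise non-negative")
        normV2 = float((V.data ** 2).sum())
    else:
        V = np.asarray(V, dtype=float)
        if V.size and V.min() < 0:
            raise ValueError("V must be elementwise non-negative")
        normV2 = float((V ** 2).sum())
    n_pixels, n_channels = V.shape
    if not (1 <= k <= min(n_pixels, n_channels)):
        raise ValueError(f"k={k} out of range for a {V.shape} matrix")
    if tol <= 0:
        raise ValueError("tol must be positive")

    rng = np.random.default_rng(seed)
    if normV2 == 0.0:
        warnings.warn("all-zero input matrix; returning zero factors")
        return NMFResult(
            W=np.zeros((n_pixels, k)), H=np.zeros((k, n_channels)), k=k,
            objective_trace=np.zeros(1), iterations=0, converged=True, seed=seed,
        )

    H = rng.uniform(0.1, 1.0, size=(k, n_channels))
    W = np.zeros((n_pixels, k))
    reseeded_w = np.zeros(k, dtype=bool)
    reseeded_h = np.zeros(k, dtype=bool)
    trace: list[float] = []
    converged = False
    eps = np.finfo(float).tiny
    it = 0
    for it in range(1, max_iter + 1):
        W = (V @ H.T) @ _pinv(H @ H.T)
        np.maximum(W, 0.0, out=W)
        for j in np.flatnonzero(~W.any(axis=0)):
            if not reseeded_w[j]:
                W[:, j] = rng.uniform(0.1, 1.0, size=n_pixels)
                reseeded_w[j] = True
                log.info("re-seeded dead W column %d at iteration %d", j, it)
        H = _pinv(W.T @ W) @ (V.T @ W).T
        np.maximum(H, 0.0, out=H)
        for j in np.flatnonzero(~H.any(axis=1)):
            if not reseeded_h[j]:
                H[j] = rng.uniform(0.1, 1.0, size=n_channels)
                reseeded_h[j] = True
                log.info("re-seeded dead H row %d at iteration %d", j, it)
        D = _objective(V, W, H, normV2)
        trace.append(D)
        if len(trace) > 1:
            prev = trace[-2]
            if abs(D - prev) / max(prev, eps) < tol:
                converged = True
                break
    return NMFResult(W=W, H=H, k=k, objective_trace=np.asarray(trace),
                     iterations=it, converged=converged, seed=seed)


def normalize_component_set(result: NMFResult, rows: int, cols: int) -> NormalizedComponents:
    """Scale spectra jointly to % of the set-wide base peak; min-max images.

    The single largest H entry across all k spectra maps to 100 %, so
    relative abundances remain comparable between components.  Each component
    image is reshaped row-major to rows x cols and min-max scaled to [0, 1]
    for display.
    """
    h_max = result.H.max() if result.H.size else 0.0
    if h_max <= 0:
        raise ValueError("degenerate result: H has no positive entries")
    spectra = result.H * (100.0 / h_max)
    images = []
    for j in range(result.k):
        img = result.W[:, j].reshape(rows, cols)
        lo, hi = img.min(), img.max()
        images.append((img - lo) / (hi - lo) if hi > lo else np.zeros_like(img))
    return NormalizedComponents(images=tuple(images), spectra=spectra)


def component_assignment(
    result: NMFResult,
    masks: dict[str, np.ndarray],
) -> tuple[dict[str, int | None], "np.ndarray", list[str]]:
    """Greedy one-to-one matching of components to ground-truth masks.

    Pairs are matched in order of descending Pearson correlation between the
    flattened component image and the 0/1 mask.  Returns the mask -> component
    mapping (None for unmatched masks when k < n_masks), the full k x n_masks
    correlation table, and the mask-name ordering of its columns.
    """
    names = list(masks)
    flat = {name: np.asarray(masks[name], dtype=float).ravel() for name in names}
    corr = np.zeros((result.k, len(names)))
    for j in range(result.k):
        w = result.W[:, j]
        for m, name in enumerate(names):
            corr[j, m] = _pearson(w, flat[name])
    assignment: dict[str, int | None] = {name: None for name in names}
    used_components: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(-corr, axis=None), corr.shape))[0]
    for j, m in order:
        name = names[m]
        if assignment[name] is None and j not in used_components:
            assignment[name] = int(j)
            used_components.add(int(j))
    unmatched = [name for name, j in assignment.items() if j is None]
    if unmatched:
        log.warning("masks without a matched component: %s", unmatched)
    return assignment, corr, names


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0
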