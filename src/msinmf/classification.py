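"""Orthogonal PLS discriminant analysis with leave-one-out cross-validation.

A single predictive latent variable after orthogonal signal correction:
class-orthogonal variation is removed from the autoscaled feature block by
``n_orth`` OSC components, then a one-component PLS regression on the
filtered block predicts the centered class code.  Fitting is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = ["OplsDaModel", "ClassificationReport", "opls_da_fit", "predict_scores",
           "loo_cross_validate", "report_metrics"]

POSITIVE_CLASS = "ET"


@dataclass(frozen=True)
class OplsDaModel:
    x_mean: np.ndarray
    x_scale: np.ndarray
    kept_features: np.ndarray       # indices surviving the zero-variance drop
    w_pred: np.ndarray              # unit-norm predictive weights
    p_pred: np.ndarray              # predictive loadings
    b: float                        # regression scalar score -> centered y
    w_orth: np.ndarray              # (n_orth, features) unit-norm weights
    p_orth: np.ndarray              # (n_orth, features) loadings
    y_mean: float
    n_orth: int
    var_x_percent: float            # cumulative captured X variance, all LVs
    var_y_percent: float            # captured (centered) Y variance

    @property
    def n_lv(self) -> int:
        return 1 + self.n_orth


@dataclass(frozen=True)
class ClassificationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    n_misclassified: int
    misclassified_ids: tuple[int, ...]
    confusion: tuple[tuple[int, int], tuple[int, int]]  # [[TP, FN], [FP, TN]]
    positive_class: str = POSITIVE_CLASS


def _coerce_y(y) -> np.ndarray:
    """Map labels to {0, 1} with the positive class ('ET' or 1) as 1."""
    y = np.asarray(y)
    if y.dtype.kind in "USO":
        return (y == POSITIVE_CLASS).astype(float)
    return (np.asarray(y, dtype=float) > 0).astype(float)


def opls_da_fit(X, y, n_orth: int = 1, autoscale: bool = True) -> OplsDaModel:
    """Fit an oPLS-DA model with 1 predictive + ``n_orth`` orthogonal LVs.

    X is autoscaled per feature (or mean-centered only with
    ``autoscale=False``); zero-variance features are dropped with a warning.
    y may be string labels (positive class ``"ET"``) or 0/1.
    """
    X = np.asarray(X, dtype=float)
    y01 = _coerce_y(y)
    if X.ndim != 2 or X.shape[0] != y01.size:
        raise ValueError("X must be (samples, features) matching y")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    classes, counts = np.unique(y01, return_counts=True)
    if classes.size < 2:
        raise ValueError("y contains a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")

    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(x_std > 0)
    if kept.size < X.shape[1]:
        log.warning("dropping %d zero-variance feature(s)", X.shape[1] - kept.size)
    if kept.size == 0:
        raise ValueError("all features have zero variance")
    x_scale = x_std[kept] if autoscale else np.ones(kept.size)
    Xc = (X[:, kept] - x_mean[kept]) / x_scale
    y_mean = float(y01.mean())
    yc = y01 - y_mean

    ssx_total = float((Xc ** 2).sum())
    ssy_total = float((yc ** 2).sum())

    # predictive weight direction from the original block
    w = Xc.T @ yc
    w /= np.linalg.norm(w)

    Xf = Xc
    w_orths, p_orths, recon = [], [], np.zeros_like(Xc)
    for _ in range(n_orth):
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # nothing orthogonal left to remove
        w_o /= norm
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        recon += np.outer(t_o, p_o)
        w_orths.append(w_o)
        p_orths.append(p_o)

    # final single-component PLS on the filtered block
    w_pred = Xf.T @ yc
    w_pred /= np.linalg.norm(w_pred)
    t_pred = Xf @ w_pred
    p_pred = Xf.T @ t_pred / (t_pred @ t_pred)
    b = float(t_pred @ yc / (t_pred @ t_pred))
    recon += np.outer(t_pred, p_pred)

    var_x = 100.0 * (1.0 - ((Xc - recon) ** 2).sum() / ssx_total) if ssx_total else 0.0
    var_y = 100.0 * (1.0 - ((yc - b * t_pred) ** 2).sum() / ssy_total) if ssy_total else 0.0

    n_feat = kept.size
    return OplsDaModel(
        x_mean=x_mean, x_scale=x_std if autoscale else np.ones_like(x_std),
        kept_features=kept,
        w_pred=w_pred, p_pred=p_pred, b=b,
        w_orth=np.asarray(w_orths).reshape(len(w_orths), n_feat),
        p_orth=np.asarray(p_orths).reshape(len(p_orths), n_feat),
        y_mean=y_mean, n_orth=len(w_orths),
        var_x_percent=float(var_x), var_y_percent=float(var_y),
    )


def predict_scores(model: OplsDaModel, X) -> np.ndarray:
    """Predicted class score on the 0/1 coding scale for each row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xc = (X[:, model.kept_features] - model.x_mean[model.kept_features]) / \
        model.x_scale[model.kept_features]
    for w_o, p_o in zip(model.w_orth, model.p_orth):
        t_o = Xc @ w_o
        Xc = Xc - np.outer(t_o, p_o)
    t = Xc @ model.w_pred
    return model.b * t + model.y_mean


def predict_labels(model: OplsDaModel, X) -> np.ndarray:
    """Threshold predicted scores at the midpoint of the 0/1 class codes.

    Exact ties go to the negative (control) class.
    """
    return (predict_scores(model, X) > 0.5).astype(int)


def loo_cross_validate(X, y, n_orth: int = 1, autoscale: bool = True) -> ClassificationReport:
    """Leave-one-out cross-validation of the full fit-and-threshold pipeline."""
    X = np.asarray(X, dtype=float)
    y01 = _coerce_y(y).astype(int)
    n = y01.size
    if n < 3:
        raise ValueError("need at least 3 samples for leave-one-out")
    tp = tn = fp = fn = 0
    missed = []
    for i in range(n):
        keep = np.arange(n) != i
        y_train = y01[keep]
        if np.unique(y_train).size < 2:
            raise ValueError(f"training fold without sample {i} has a single class")
        model = opls_da_fit(X[keep], y_train, n_orth=n_orth, autoscale=autoscale)
        pred = int(predict_labels(model, X[i:i + 1])[0])
        truth = int(y01[i])
        if truth == 1 and pred == 1:
            tp += 1
        elif truth == 1:
            fn += 1
            missed.append(i)
        elif pred == 0:
            tn += 1
        else:
            fp += 1
            missed.append(i)
    return report_metrics(tp=tp, fn=fn, tn=tn, fp=fp, misclassified_ids=tuple(missed))


def report_metrics(
    tp: int, fn: int, tn: int, fp: int,
    misclassified_ids: tuple[int, ...] = (),
) -> ClassificationReport:
    """Accuracy / sensitivity / specificity (percent, 1 decimal) from counts."""
    for name, v in (("TP", tp), ("FN", fn), ("TN", tn), ("FP", fp)):
        if v < 0:
            raise ValueError(f"negative {name} count")
    n = tp + fn + tn + fp
    if n == 0:
        raise ValueError("empty confusion table")
    acc = round(100.0 * (tp + tn) / n, 1)
    sens = round(100.0 * tp / (tp + fn), 1) if (tp + fn) else 0.0
    spec = round(100.0 * tn / (tn + fp), 1) if (tn + fp) else 0.0
    return ClassificationReport(
        accuracy=acc, sensitivity=sens, specificity=spec,
        n_misclassified=fn + fp, misclassified_ids=misclassified_ids,
        confusion=((tp, fn), (fp, tn)),
    )
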