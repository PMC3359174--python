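"""Linear discriminant analysis with pooled covariance and equal priors.

The classifier assigns a sample x to the class maximizing the linear
discriminant score

    delta_c(x) = x' S^-1 m_c - 1/2 m_c' S^-1 m_c + log pi_c

where m_c are per-class sample means and S is the within-class scatter
normalized by (n - k), optionally ridge-regularized. Priors default to
equal: the study scores with adjusted (class-balanced) accuracy, and
empirical priors would bias decisions toward the over-represented
no-control class. Ties break deterministically toward the earlier class in
label order.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg


@dataclass(eq=False)
class LdaModel:
    classes: np.ndarray  # (k,) ordered class labels
    means: np.ndarray  # (k, p)
    covariance: np.ndarray  # (p, p) pooled within-class covariance (+ ridge)
    priors: np.ndarray  # (k,)
    _weights: np.ndarray | None = None  # (p, k) cached S^-1 m_c'

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def _auto_ridge(cov: np.ndarray) -> float:
    p = cov.shape[0]
    return 1e-6 * float(np.trace(cov)) / max(p, 1)


def lda_fit(
    X: np.ndarray,
    y: Sequence,
    ridge: float | str = "auto",
    priors: np.ndarray | str = "equal",
) -> LdaModel:
    """Fit the pooled-covariance LDA model.

    ``ridge`` is added to the covariance diagonal; ``"auto"`` uses
    1e-6 * trace(S)/p, enough to guarantee invertibility at the subset
    dimensionalities used here (<= 12 features, ~240 training samples).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    classes, y_idx = np.unique(y, return_inverse=True)
    k = classes.size
    n, p = X.shape
    if k < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(y_idx, minlength=k)
    if counts.min() < 2:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small!r} has fewer than 2 samples")
    if n <= p:
        warnings.warn(
            f"fewer samples ({n}) than features ({p}); covariance estimate is degenerate",
            stacklevel=2,
        )
    means = np.stack([X[y_idx == j].mean(axis=0) for j in range(k)])
    Xc = X - means[y_idx]
    cov = (Xc.T @ Xc) / (n - k)
    lam = _auto_ridge(cov) if ridge == "auto" else float(ridge)
    if lam < 0:
        raise ValueError("ridge must be non-negative")
    cov = cov + lam * np.eye(p)
    if isinstance(priors, str):
        if priors == "equal":
            pri = np.full(k, 1.0 / k)
        elif priors == "empirical":
            pri = counts / n
        else:
            raise ValueError(f"unknown priors option {priors!r}")
    else:
        pri = np.asarray(priors, dtype=float)
        if pri.shape != (k,) or not np.isclose(pri.sum(), 1.0):
            raise ValueError("priors must have one entry per class and sum to 1")
    try:
        cho = linalg.cho_factor(cov)
        weights = linalg.cho_solve(cho, means.T)  # (p, k)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "pooled covariance is singular; refit with ridge > 0 "
            "(e.g. ridge='auto')"
        ) from exc
    return LdaModel(classes=classes, means=means, covariance=cov, priors=pri,
                    _weights=weights)


def _scores(model: LdaModel, X: np.ndarray) -> np.ndarray:
    """Discriminant scores -1/2 (x-m_c)' S^-1 (x-m_c) + log pi_c.

    Algebraically equal (up to the class-independent term -1/2 x' S^-1 x)
    to the linear form x' S^-1 m_c - 1/2 m_c' S^-1 m_c + log pi_c, but the
    symmetric quadratic keeps genuinely equidistant samples exactly tied in
    floating point, so the class-order tie-break is honoured.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[-1] if X.ndim == 2 else '?'} does not match "
            f"model dimension {model.n_features}"
        )
    cho = linalg.cho_factor(model.covariance)
    scores = np.empty((X.shape[0], model.classes.size))
    for j, mean in enumerate(model.means):
        diff = X - mean
        d2 = np.einsum("ij,ij->i", diff, linalg.cho_solve(cho, diff.T).T)
        scores[:, j] = -0.5 * d2 + np.log(model.priors[j])
    return scores


def lda_predict(model: LdaModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and per-class discriminant scores.

    Ties resolve to the earliest class in ``model.classes`` (argmax keeps
    the first maximum).
    """
    scores = _scores(model, X)
    return model.classes[scores.argmax(axis=1)], scores


def per_class_correct(y_true, y_pred, classes) -> np.ndarray:
    """Fraction correct within each class, in ``classes`` order."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out = np.empty(len(classes))
    for j, c in enumerate(classes):
        mask = y_true == c
        out[j] = (y_pred[mask] == c).mean() if mask.any() else np.nan
    return out


def error_rate(model: LdaModel, X: np.ndarray, y) -> float:
    """Mean probability of error: class-averaged misclassification rate.

    Equals 1 minus the adjusted accuracy (as a proportion); used as the GA
    fitness value, estimated by resubstitution on the training set.
    """
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("labels are empty")
    pred, _ = lda_predict(model, X)
    rates = per_class_correct(y, pred, model.classes)
    return float(1.0 - np.nanmean(rates))


def resubstitution_error_fitness(X: np.ndarray, y, ridge: float | str = "auto"):
    """Fast closure: subset indices -> LDA resubstitution mean error.

    Precomputes class partitions once; each call fits equal-prior LDA on the
    column subset and scores it on the same (training) data. This is the
    fitness function evaluated thousands of times inside the GA, so it
    avoids re-validating inputs per call.
    """
    X = np.asarray(X, dtype=float)
    classes, y_idx = np.unique(np.asarray(y), return_inverse=True)
    k = classes.size
    rows = [np.flatnonzero(y_idx == j) for j in range(k)]
    n = X.shape[0]

    def fitness(indices) -> float:
        Xs = X[:, list(indices)]
        p = Xs.shape[1]
        means = np.stack([Xs[r].mean(axis=0) for r in rows])
        Xc = Xs - means[y_idx]
        cov = (Xc.T @ Xc) / (n - k)
        lam = _auto_ridge(cov) if ridge == "auto" else float(ridge)
        cov[np.diag_indices(p)] += lam
        W = np.linalg.solve(cov, means.T)
        scores = Xs @ W - 0.5 * np.sum(means.T * W, axis=0)
        pred = scores.argmax(axis=1)
        correct = [np.mean(pred[r] == j) for j, r in enumerate(rows)]
        return float(1.0 - np.mean(correct))

    return fitness
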