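"""Flexible discriminant analysis (FDA) and its phylogenetic variant (pFDA).

FDA is implemented by optimal scoring: class indicators are regressed
on the predictors, the score directions come from the eigenstructure of
the fitted indicator cross-products, and observations are classified by
the Gaussian (LDA) rule on the discriminant variates with class-
frequency priors. With no whitening this is exactly linear discriminant
analysis; the optimal-scoring formulation is kept because the
phylogenetic variant needs real-valued (whitened) "indicators".

pFDA whitens both predictors and class indicators by the inverse square
root of a lambda-scaled Brownian covariance C(lambda) (off-diagonals
multiplied by lambda, Pagel-style), with lambda fitted by maximizing
the multivariate Brownian likelihood of the predictors. At lambda = 0
on an ultrametric tree the whitening is a scalar and pFDA reduces to
FDA on the same rows.

Classification tasks use at most three predictors, reflecting the
standard three-metric subsets: the most size-correlated metrics
(Tb.Th, CSA, Conn.D), the least size-correlated (BV.TV, GC, DA), and
the most phylogenetically correlated (DA, Tb.Th, CSA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ClassificationTask",
    "ClassificationResult",
    "METRIC_SUBSETS",
    "fda",
    "pfda",
    "estimate_lambda",
]

METRIC_SUBSETS = {
    "size": ("tb_th", "csa", "conn_d"),
    "least_size": ("bv_tv", "gc", "da"),
    "phylo": ("da", "tb_th", "csa"),
}


@dataclass(frozen=True)
class ClassificationTask:
    predictors: tuple[str, ...]
    label_column: str  # e.g. "size_class" or "ecology"
    position: str = "pooled"  # ps1..ps6 or "pooled"

    def __post_init__(self):
        if not (1 <= len(self.predictors) <= 3):
            raise ValueError("tasks use between one and three predictors")


@dataclass
class ClassificationResult:
    predicted: np.ndarray
    accuracy: float
    confusion: pd.DataFrame
    lambda_: float | None = None
    loo_accuracy: float | None = None
    classes: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")


def _confusion(true_labels, predicted, classes) -> pd.DataFrame:
    mat = pd.DataFrame(0, index=list(classes), columns=list(classes))
    for t, p in zip(true_labels, predicted):
        mat.loc[t, p] += 1
    mat.index.name = "true"
    mat.columns.name = "predicted"
    return mat


def _ridge_if_singular(W: np.ndarray) -> np.ndarray:
    cond = np.linalg.cond(W)
    if not np.isfinite(cond) or cond > 1e10:
        warnings.warn("singular within-class covariance; adding ridge jitter")
        W = W + 1e-8 * (np.trace(W) / len(W) + 1e-12) * np.eye(len(W))
    return W


def _fit_discriminant(X: np.ndarray, Ystar: np.ndarray, Xstar: np.ndarray):
    """Optimal-scoring directions from (possibly whitened) X*, Y*.

    Regresses Y* on [1*, X*] and eigen-decomposes the indicator
    cross-products; returns the predictor coefficient matrix whose
    columns span the discriminant space.
    """
    n = len(Xstar)
    design = np.column_stack([np.ones(n), Xstar])
    B, *_ = np.linalg.lstsq(design, Ystar, rcond=None)
    Yhat = design @ B
    M = np.linalg.solve(Ystar.T @ Ystar + 1e-12 * np.eye(Ystar.shape[1]), Ystar.T @ Yhat)
    evals, evecs = np.linalg.eig(M)
    order = np.argsort(evals.real)[::-1]
    k = min(Ystar.shape[1] - 1, X.shape[1])
    theta = evecs.real[:, order[:k]]
    coefs = B[1:, :] @ theta  # predictor part only
    return coefs


def _gaussian_rule(Z: np.ndarray, labels: np.ndarray, classes) -> tuple:
    """LDA rule on the discriminant variates with frequency priors."""
    n, k = Z.shape
    means = np.vstack([Z[labels == c].mean(axis=0) for c in classes])
    priors = np.array([(labels == c).mean() for c in classes])
    W = np.zeros((k, k))
    for i, c in enumerate(classes):
        d = Z[labels == c] - means[i]
        W += d.T @ d
    W /= max(n - len(classes), 1)
    W = _ridge_if_singular(W)
    Wi = np.linalg.inv(W)
    return means, priors, Wi


def _classify(Z, means, priors, Wi, classes) -> np.ndarray:
    scores = Z @ Wi @ means.T - 0.5 * np.einsum("jk,kl,jl->j", means, Wi, means)
    scores = scores + np.log(priors)
    return np.asarray(classes)[np.argmax(scores, axis=1)]


def _run(X: np.ndarray, labels: np.ndarray, whiten: np.ndarray | None):
    classes = tuple(pd.unique(labels))
    Y = np.column_stack([(labels == c).astype(float) for c in classes])
    if whiten is None:
        Xstar, Ystar = X, Y
    else:
        Xstar, Ystar = whiten @ X, whiten @ Y
    coefs = _fit_discriminant(X, Ystar, Xstar)
    Z = Xstar @ coefs
    means, priors, Wi = _gaussian_rule(Z, labels, classes)
    predicted = _classify(Z, means, priors, Wi, classes)
    return predicted, classes


def _prepare(task: ClassificationTask, data: pd.DataFrame):
    X = data[list(task.predictors)].to_numpy(float)
    labels = data[task.label_column].to_numpy()
    if len(pd.unique(labels)) < 2:
        raise ValueError("need at least two classes")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("each class needs at least 2 observations")
    return X, labels


def fda(
    task: ClassificationTask, data: pd.DataFrame, leave_one_out: bool = False
) -> ClassificationResult:
    """Linear FDA; accuracy is the resubstitution correct-classification
    rate (leave-one-out optionally reported alongside)."""
    X, labels = _prepare(task, data)
    predicted, classes = _run(X, labels, whiten=None)
    acc = float((predicted == labels).mean())
    loo = None
    if leave_one_out:
        hits = 0
        for i in range(len(X)):
            keep = np.arange(len(X)) != i
            if len(pd.unique(labels[keep])) < 2:
                continue
            pred_i, cls = _run(X[keep], labels[keep], whiten=None)
            # refit and classify the held-out row
            coefs = _fit_discriminant(
                X[keep],
                np.column_stack([(labels[keep] == c).astype(float) for c in cls]),
                X[keep],
            )
            Z = X[keep] @ coefs
            means, priors, Wi = _gaussian_rule(Z, labels[keep], cls)
            pred = _classify(X[[i]] @ coefs, means, priors, Wi, cls)
            hits += int(pred[0] == labels[i])
        loo = hits / len(X)
    return ClassificationResult(
        predicted=predicted,
        accuracy=acc,
        confusion=_confusion(labels, predicted, classes),
        loo_accuracy=loo,
        classes=classes,
    )


# ---------------------------------------------------------------------------
# Phylogenetic variant


def _c_lambda(C: np.ndarray, lam: float) -> np.ndarray:
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def _brownian_loglik(X: np.ndarray, C: np.ndarray, lam: float) -> float:
    """Profile log-likelihood of the predictors under MVN(mu, sigma^2 C(lambda))."""
    Cl = _c_lambda(C, lam)
    evals = np.linalg.eigvalsh(Cl)
    if evals.min() <= 0:
        return -np.inf
    Ci = np.linalg.inv(Cl)
    logdet = float(np.sum(np.log(evals)))
    n = len(X)
    ones = np.ones(n)
    denom = float(ones @ Ci @ ones)
    ll = 0.0
    for t in range(X.shape[1]):
        y = X[:, t]
        mu = float(ones @ Ci @ y) / denom
        d = y - mu
        s2 = float(d @ Ci @ d) / n
        ll += -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return ll


def estimate_lambda(
    predictors: np.ndarray, C: np.ndarray, grid: int = 21
) -> float:
    """Pagel's lambda for the predictor block: grid search on [0, 1]
    followed by bounded refinement of the Brownian log-likelihood."""
    X = np.asarray(predictors, float)
    lams = np.linspace(0.0, 1.0, grid)
    lls = [_brownian_loglik(X, C, l) for l in lams]
    best = int(np.argmax(lls))
    lo = lams[max(best - 1, 0)]
    hi = lams[min(best + 1, grid - 1)]
    if hi - lo < 1e-12:
        return float(lams[best])
    res = optimize.minimize_scalar(
        lambda l: -_brownian_loglik(X, C, l), bounds=(lo, hi), method="bounded"
    )
    lam = float(res.x)
    if -res.fun < max(lls):  # refinement may not beat the grid at the edges
        lam = float(lams[best])
    if not np.isfinite(_brownian_loglik(X, C, lam)):
        warnings.warn("C(lambda) not positive definite; clamping lambda")
        lam = float(lams[best])
    return min(max(lam, 0.0), 1.0)


def _inv_sqrt(C: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    evals, evecs = np.linalg.eigh(C)
    evals = np.clip(evals, floor, None)
    return evecs @ np.diag(evals**-0.5) @ evecs.T


def pfda(
    task: ClassificationTask,
    data: pd.DataFrame,
    C: np.ndarray,
    lam: float | None = None,
) -> ClassificationResult:
    """Phylogenetic FDA on species rows aligned with the covariance C.

    Predictors and class indicators are whitened by C(lambda)^(-1/2)
    and the discriminant is fit and evaluated on the transformed data;
    accuracy is the resubstitution rate. lambda defaults to the
    Brownian-likelihood estimate from the predictors.
    """
    X, labels = _prepare(task, data)
    C = np.asarray(C, float)
    if C.shape != (len(X), len(X)):
        raise ValueError("C must align with the data rows (one row per species)")
    if lam is None:
        lam = estimate_lambda(X, C)
    W = _inv_sqrt(_c_lambda(C, lam))
    predicted, classes = _run(X, labels, whiten=W)
    acc = float((predicted == labels).mean())
    return ClassificationResult(
        predicted=predicted,
        accuracy=acc,
        confusion=_confusion(labels, predicted, classes),
        lambda_=float(lam),
        classes=classes,
    )
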