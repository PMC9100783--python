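"""L2-regularized logistic regression.

The classifier minimizes, over coefficients ``w`` (labels coded +/-1),

    sum_i log(1 + exp(-w^T x_i * y_i)) + lambda * w^T w,

with ``lambda = 1`` throughout the reference analysis.  The solve is
delegated to scikit-learn's LogisticRegression: its objective
``0.5 ||w||^2 + C * sum_i log(...)`` is proportional to the one above when
``C = 1 / (2 * lambda)``.  The intercept, when enabled (default), is
unpenalized — standard practice; the penalized-objective form has none, so
it can be switched off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

__all__ = ["LogisticModel", "fit_logistic_l2", "logistic_objective"]


@dataclass
class LogisticModel:
    """Fitted coefficients of the penalized logistic model."""

    w: np.ndarray
    intercept: float
    lam: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.w)) or not np.isfinite(self.intercept):
            raise ValueError("non-finite coefficients")

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted labels in {0, 1}."""
        return (self.decision_function(X) > 0).astype(int)


def logistic_objective(
    w: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    intercept: float = 0.0,
) -> float:
    """The penalized objective at ``w`` (``y`` in {-1, +1}; intercept
    unpenalized)."""
    y = np.asarray(y, dtype=float)
    margins = -(X @ w + intercept) * y
    # numerically stable log(1 + exp(m))
    return float(np.logaddexp(0.0, margins).sum() + lam * np.dot(w, w))


def _to_pm1(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    u = set(np.unique(y))
    if u <= {0, 1}:
        return np.where(y == 1, 1.0, -1.0)
    if u <= {-1, 1}:
        return y.astype(float)
    raise ValueError("labels must be 0/1 or -1/+1")


def fit_logistic_l2(
    X: np.ndarray,
    y: np.ndarray,
    lam: float = 1.0,
    *,
    fit_intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> LogisticModel:
    """Fit the L2-penalized logistic model (lambda = 1 by default).

    Accepts 0/1 or -1/+1 labels (coded +/-1 internally, as the objective
    requires); both classes must be present and ``X`` finite.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in X")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    ypm = _to_pm1(y)
    if ypm.min() == ypm.max():
        raise ValueError("both classes must be present")
    clf = LogisticRegression(
        C=1.0 / (2.0 * lam),  # L2 penalty (the sklearn default)
        solver="lbfgs",
        fit_intercept=fit_intercept,
        tol=tol,
        max_iter=max_iter,
    )
    clf.fit(X, (ypm > 0).astype(int))
    w = clf.coef_.ravel().astype(float)
    b = float(clf.intercept_[0]) if fit_intercept else 0.0
    return LogisticModel(w, b, lam)
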