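"""Single-response partial least squares regression with venetian-blind CV.

The PLS implementation is NIPALS for one response: per component the weight
vector is X'y (normalized), scores and loadings follow, and X and y are
deflated.  For a single response no inner iteration is required, so each
component is a closed-form pass.  Regression coefficient vectors are kept
for every component count 1..A_max, so cross-validation curves and models
of different complexity come from one fit.

Cross-validation uses venetian blinds: sample i (in dataset order) belongs
to fold i mod k.  With samples randomized at measurement time this gives
interleaved, near-balanced folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class CalibrationModel:
    """Fitted PLS model with coefficient vectors for all component counts.

    ``coefficients[:, a-1]`` applied to centered X reproduces the fitted
    values of the a-component model; ``predict(X, a)`` adds the centering
    back in.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # p × A
    loadings: np.ndarray      # p × A
    scores: np.ndarray        # n × A
    y_loadings: np.ndarray    # A
    coefficients: np.ndarray  # p × A
    a_max: int
    chosen_a: int | None = None
    selected_channels: np.ndarray | None = None
    preprocessing: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray, a: int | None = None) -> np.ndarray:
        a = a or self.chosen_a or self.a_max
        if not 1 <= a <= self.a_max:
            raise ValueError(f"component count {a} outside 1..{self.a_max}")
        X = np.asarray(X, dtype=float)
        if self.selected_channels is not None and X.shape[1] != len(self.x_mean):
            X = X[:, self.selected_channels]
        return self.y_mean + (X - self.x_mean) @ self.coefficients[:, a - 1]

    def fitted(self, X: np.ndarray, a: int | None = None) -> np.ndarray:
        return self.predict(X, a)


def pls_fit(X: np.ndarray, y: np.ndarray, a_max: int) -> CalibrationModel:
    """NIPALS PLS1 on column-centered X and centered y.

    Deflates X and y per component; stores weights, loadings, scores and the
    coefficient vector for every component count up to ``a_max``.  If a
    component's weight norm falls below 1e−12 (X fully deflated), the model
    is truncated there with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if y.shape != (n,):
        raise ValueError("y length must match number of rows of X")
    if np.std(y) == 0:
        raise ValueError("response has zero variance")
    if a_max < 1 or a_max > min(n - 1, p):
        raise ValueError(f"a_max must be in 1..min(n-1, p) = {min(n - 1, p)}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean

    W = np.zeros((p, a_max))
    P = np.zeros((p, a_max))
    T = np.zeros((n, a_max))
    q = np.zeros(a_max)
    actual = a_max
    for a in range(a_max):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            warnings.warn(f"X deflated after {a} components; truncating a_max", stacklevel=2)
            actual = a
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        pa = Xd.T @ t / tt
        qa = float(yd @ t / tt)
        Xd -= np.outer(t, pa)
        yd -= qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
    if actual == 0:
        raise ValueError("X carries no covariance with y (zero first weight)")
    W, P, T, q = W[:, :actual], P[:, :actual], T[:, :actual], q[:actual]

    # B_a = W_a (P_a' W_a)^{-1} q_a, built incrementally per component count
    coefs = np.zeros((p, actual))
    for a in range(1, actual + 1):
        Ra = W[:, :a] @ np.linalg.inv(P[:, :a].T @ W[:, :a])
        coefs[:, a - 1] = Ra @ q[:a]
    return CalibrationModel(x_mean=x_mean, y_mean=y_mean, weights=W, loadings=P,
                            scores=T, y_loadings=q, coefficients=coefs, a_max=actual)


def venetian_blinds(n: int, k: int = 7) -> np.ndarray:
    """Fold assignment: sample i (0-based, dataset order) → fold i mod k."""
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    return np.arange(n) % k


@dataclass
class CVResult:
    """Cross-validation curves and per-sample predictions per component count."""

    rmsecv: np.ndarray       # A
    r2cv: np.ndarray         # A
    folds: np.ndarray        # n
    predictions: np.ndarray  # n × A
    a_max: int

    @property
    def best_a(self) -> int:
        return int(np.argmin(self.rmsecv)) + 1

    @property
    def best_rmsecv(self) -> float:
        return float(np.min(self.rmsecv))


def cross_validate(X: np.ndarray, y: np.ndarray, a_max: int, k: int = 7,
                   folds: np.ndarray | None = None) -> CVResult:
    """Venetian-blind k-fold CV of PLS1 at every component count ≤ a_max.

    Each fold is predicted by a model fitted on the remaining samples;
    RMSECV(a) is the root mean squared CV residual and R²_cv(a) uses the
    full-data mean in the denominator.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    folds = venetian_blinds(n, k) if folds is None else np.asarray(folds)
    # every fold's training split must support a components: a ≤ n_train − 1
    a_eff = min(a_max, min(n - int(np.bincount(folds).max()) - 1, X.shape[1]))
    if a_eff < 1:
        raise ValueError("too few samples per training split for one component")
    preds = np.full((n, a_eff), np.nan)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        if np.std(y[train]) == 0:
            raise ValueError(f"training split for fold {f} has zero-variance y")
        model = pls_fit(X[train], y[train], a_eff)
        for a in range(1, model.a_max + 1):
            preds[test, a - 1] = model.predict(X[test], a)
        if model.a_max < a_eff:  # truncated fit: pad with its deepest model
            for a in range(model.a_max + 1, a_eff + 1):
                preds[test, a - 1] = model.predict(X[test], model.a_max)
    resid = preds - y[:, None]
    rmsecv = np.sqrt(np.mean(resid**2, axis=0))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2cv = 1.0 - np.sum(resid**2, axis=0) / ss_tot
    return CVResult(rmsecv=rmsecv, r2cv=r2cv, folds=folds, predictions=preds,
                    a_max=a_eff)


def select_components(cv: CVResult, rule: str = "min", tol: float = 0.01) -> int:
    """Choose the component count from a CV curve.

    ``min``: global minimum RMSECV.  ``parsimonious``: the smallest a whose
    RMSECV is within (1+tol) of the minimum.  Ties go to the smaller a.
    """
    if cv.rmsecv.size == 0:
        raise ValueError("empty CV result")
    if rule == "min":
        return int(np.argmin(cv.rmsecv)) + 1
    if rule == "parsimonious":
        thresh = (1.0 + tol) * float(np.min(cv.rmsecv))
        return int(np.argmax(cv.rmsecv <= thresh)) + 1
    raise ValueError(f"unknown rule {rule!r}")


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """R² with the global-mean denominator (the package-wide convention)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero-variance reference")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot
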