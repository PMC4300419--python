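"""Latent-variable engines: PCA and NIPALS PLS with the chemometric
diagnostics used throughout the model-building protocol.

Conventions
-----------
- Matrices arrive preprocessed (autoscaled descriptors); both engines still
  mean-center internally so they are well defined on raw input too.
- Component sign: the loading entry of largest magnitude is made positive,
  so reports are reproducible across runs and platforms.
- Cross-validated predictive power Q^2 = 1 - PRESS/SS, with SS taken about
  the full-data response mean and folds assigned round-robin by observation
  index ("venetian blinds") into 7 groups by default.
- VIP_j = sqrt( p * sum_a SSY_a (w_aj/||w_a||)^2 / sum_a SSY_a ) with
  SSY_a = q_a^2 t_a't_a, the response variance captured by component a;
  the squared VIPs average to exactly 1.
- DModX of an observation is its residual standard deviation over the
  pooled model residual standard deviation; under normal residuals its
  square is F(p-A, (n-A-1)(p-A)) distributed, which provides the 95% limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "NipalsPLS",
    "PCAModel",
    "CVResult",
    "q2_crossval",
    "choose_components",
    "vip",
    "hotelling_t2",
    "dmodx",
]


class ModelError(ValueError):
    pass


def _as_matrix(X) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(map(str, X.columns)), list(map(str, X.index))
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ModelError("X must be two-dimensional")
    return arr, [f"x{j}" for j in range(arr.shape[1])], [str(i) for i in range(arr.shape[0])]


def _fix_signs(W, P, q, T):
    """Largest-magnitude X-loading positive, per component."""
    for a in range(P.shape[1]):
        j = np.argmax(np.abs(P[:, a]))
        if P[j, a] < 0:
            W[:, a] *= -1
            P[:, a] *= -1
            T[:, a] *= -1
            q[a] *= -1
    return W, P, q, T


class NipalsPLS(RegressorMixin, BaseEstimator):
    """PLS1 regression fitted by NIPALS with deflation.

    Parameters
    ----------
    n_components : int
        Number of latent components A.
    tol, max_iter : float, int
        Convergence tolerance and iteration cap per component. For a single
        response the inner loop converges in one pass; the machinery is kept
        so the fit is well defined for multi-column responses as well.

    Fitted attributes (training-centered quantities):
    ``x_weights_`` W (p x A), ``x_loadings_`` P (p x A), ``y_loadings_`` q
    (A,), ``x_scores_`` T (n x A), ``coef_`` (p,), and the training
    statistics ``r2_`` and ``rmse_tr_``.
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-12, max_iter: int = 500):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        Xv, names, row_names = _as_matrix(X)
        yv = np.asarray(y, dtype=float).ravel()
        n, p = Xv.shape
        if yv.shape[0] != n:
            raise ModelError("X and y have different numbers of observations")
        a_req = int(self.n_components)
        if a_req < 1 or a_req > min(n - 1, p):
            raise ModelError(f"n_components={a_req} exceeds min(n-1, p)={min(n - 1, p)}")
        if np.var(yv) < 1e-15:
            raise ModelError("response has zero variance")

        self.feature_names_in_ = names
        self.x_mean_ = Xv.mean(axis=0)
        self.y_mean_ = float(yv.mean())
        E = Xv - self.x_mean_
        f = yv - self.y_mean_

        W = np.zeros((p, a_req))
        P = np.zeros((p, a_req))
        q = np.zeros(a_req)
        T = np.zeros((n, a_req))
        fitted_a = 0
        for a in range(a_req):
            w = E.T @ f
            norm = np.linalg.norm(w)
            if norm < 1e-14:  # residual X carries no covariance with y
                break
            w /= norm
            t = E @ w
            for _ in range(self.max_iter):
                # PLS1: the score vector u equals the response residual, so
                # the weight update is stationary after one pass; re-derive
                # t until it stops moving.
                w_new = E.T @ f
                w_new /= np.linalg.norm(w_new)
                t_new = E @ w_new
                converged = np.linalg.norm(t_new - t) <= self.tol * max(1.0, np.linalg.norm(t))
                w, t = w_new, t_new
                if converged:
                    break
            tt = float(t @ t)
            if tt < 1e-14:
                break
            p_a = E.T @ t / tt
            q_a = float(f @ t / tt)
            E = E - np.outer(t, p_a)
            f = f - q_a * t
            W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
            fitted_a += 1
        if fitted_a == 0:
            raise ModelError("no latent component could be extracted")
        W, P, q, T = W[:, :fitted_a], P[:, :fitted_a], q[:fitted_a], T[:, :fitted_a]
        W, P, q, T = _fix_signs(W, P, q, T)

        self.n_components_ = fitted_a
        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = q
        self.x_scores_ = T
        self.x_residuals_ = E
        self.row_names_ = row_names
        self._update_coef()
        yhat = self.predict(X)
        ss = float(np.sum((yv - self.y_mean_) ** 2))
        press = float(np.sum((yv - yhat) ** 2))
        self.fitted_ = yhat
        self.r2_ = 1.0 - press / ss
        self.rmse_tr_ = float(np.sqrt(press / n))
        return self

    def _update_coef(self, a: int | None = None) -> np.ndarray:
        """Closed-form regression vector B = W (P'W)^-1 q for a components."""
        a = self.n_components_ if a is None else a
        W, P, q = self.x_weights_[:, :a], self.x_loadings_[:, :a], self.y_loadings_[:a]
        B = W @ np.linalg.solve(P.T @ W, q)
        if a == self.n_components_:
            self.coef_ = B
        return B

    def _centered(self, X) -> np.ndarray:
        Xv, names, _ = _as_matrix(X)
        if isinstance(X, pd.DataFrame):
            if names != self.feature_names_in_:
                if set(names) != set(self.feature_names_in_):
                    raise ModelError("descriptor columns do not match the fitted model")
                Xv = X.loc[:, self.feature_names_in_].to_numpy(dtype=float)
        elif Xv.shape[1] != len(self.feature_names_in_):
            raise ModelError("descriptor count does not match the fitted model")
        return Xv - self.x_mean_

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        a = self.n_components_ if n_components is None else int(n_components)
        if not 1 <= a <= self.n_components_:
            raise ModelError(f"n_components must be in [1, {self.n_components_}]")
        B = self.coef_ if a == self.n_components_ else self._update_coef(a)
        return self.y_mean_ + self._centered(X) @ B

    def transform(self, X) -> np.ndarray:
        """Scores of new observations, with sequential deflation."""
        E = self._centered(X)
        T = np.zeros((E.shape[0], self.n_components_))
        for a in range(self.n_components_):
            t = E @ self.x_weights_[:, a]
            E = E - np.outer(t, self.x_loadings_[:, a])
            T[:, a] = t
        return T

    def x_residual(self, X) -> np.ndarray:
        """X-block residual after projecting onto the model plane."""
        E = self._centered(X)
        for a in range(self.n_components_):
            t = E @ self.x_weights_[:, a]
            E = E - np.outer(t, self.x_loadings_[:, a])
        return E


class PCAModel(BaseEstimator):
    """Principal component analysis on mean-centered data via SVD.

    Fitted attributes: ``loadings_`` (p x k, orthonormal columns),
    ``scores_`` (n x k), ``explained_variance_`` (per component, (n-1)
    denominator) and ``explained_variance_ratio_``.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        Xv, names, row_names = _as_matrix(X)
        n, p = Xv.shape
        k = int(self.n_components)
        if k < 1 or k > min(n - 1, p):
            raise ModelError(f"n_components={k} exceeds min(n-1, p)={min(n - 1, p)}")
        self.feature_names_in_ = names
        self.row_names_ = row_names
        self.x_mean_ = Xv.mean(axis=0)
        Xc = Xv - self.x_mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        loadings = Vt[:k].T
        scores = U[:, :k] * s[:k]
        for a in range(k):  # sign convention
            j = np.argmax(np.abs(loadings[:, a]))
            if loadings[j, a] < 0:
                loadings[:, a] *= -1
                scores[:, a] *= -1
        self.loadings_ = loadings
        self.scores_ = scores
        self.x_residuals_ = Xc - scores @ loadings.T
        self.singular_values_ = s[:k]
        self.n_components_ = k
        total_var = float(np.sum(s**2)) / (n - 1)
        self.explained_variance_ = s[:k] ** 2 / (n - 1)
        self.explained_variance_ratio_ = (
            self.explained_variance_ / total_var if total_var > 0
            else np.zeros(k))
        self.n_samples_ = n
        return self

    def transform(self, X) -> np.ndarray:
        Xv, names, _ = _as_matrix(X)
        if isinstance(X, pd.DataFrame) and names != self.feature_names_in_:
            Xv = X.loc[:, self.feature_names_in_].to_numpy(dtype=float)
        return (Xv - self.x_mean_) @ self.loadings_

    def x_residual(self, X) -> np.ndarray:
        Xv, names, _ = _as_matrix(X)
        if isinstance(X, pd.DataFrame) and names != self.feature_names_in_:
            Xv = X.loc[:, self.feature_names_in_].to_numpy(dtype=float)
        Xc = Xv - self.x_mean_
        return Xc - (Xc @ self.loadings_) @ self.loadings_.T

    @property
    def x_scores_(self) -> np.ndarray:
        return self.scores_


# ---------------------------------------------------------------------------
# diagnostics


def hotelling_t2(model, X=None, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Hotelling T^2 in score space and its F-based critical limit.

    T^2_i = sum_a t_ia^2 / s_a^2 with s_a^2 the (n-1) variance of the
    training scores; the limit is A(n^2-1)/(n(n-A)) F_(1-alpha)(A, n-A).
    """
    T_train = model.x_scores_
    n, A = T_train.shape
    s2 = T_train.var(axis=0, ddof=1)
    T = T_train if X is None else model.transform(X)
    t2 = np.sum(T**2 / s2, axis=1)
    fcrit = stats.f.ppf(1 - alpha, A, n - A)
    limit = A * (n**2 - 1) / (n * (n - A)) * fcrit
    return t2, float(limit)


def dmodx(model, X=None, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Normalized distance to the model in X-space and its 95% limit.

    The observation residual standard deviation (over p-A residual degrees
    of freedom) is divided by the pooled training residual standard
    deviation (over (n-A-1)(p-A) degrees of freedom). The critical limit is
    sqrt(F_(1-alpha)(p-A, (n-A-1)(p-A))).
    """
    E_train = model.x_residuals_
    n, p = E_train.shape
    A = model.n_components_
    m = p - A
    M = (n - A - 1) * m
    if m <= 0 or M <= 0:
        raise ModelError("too few residual degrees of freedom for DModX")
    s0 = np.sqrt(np.sum(E_train**2) / M)
    E = E_train if X is None else model.x_residual(X)
    s_obs = np.sqrt(np.sum(E**2, axis=1) / m)
    limit = float(np.sqrt(stats.f.ppf(1 - alpha, m, M)))
    if s0 < 1e-300:
        return np.where(s_obs > 0, np.inf, 0.0), limit
    return s_obs / s0, limit


@dataclass
class CVResult:
    """Cross-validation record: fold assignment, PRESS and Q^2 profiles."""

    fold_assignment: np.ndarray
    press: np.ndarray          # PRESS at 1..A components
    q2: np.ndarray             # cumulative Q^2 at 1..A components
    chosen: int = 0

    @property
    def q2_at_chosen(self) -> float:
        return float(self.q2[self.chosen - 1]) if self.chosen else float("nan")


def _fold_assignment(n: int, groups: int, rule: str) -> np.ndarray:
    if groups > n:
        raise ModelError(f"more folds ({groups}) than observations ({n})")
    idx = np.arange(n)
    if rule == "venetian":
        return idx % groups
    if rule == "blocks":
        return np.floor(idx * groups / n).astype(int)
    raise ModelError(f"unknown fold assignment rule {rule!r}")


def q2_crossval(X, y, n_components: int, groups: int = 7,
                assignment_rule: str = "venetian") -> CVResult:
    """Grouped cross-validated Q^2 profile for 1..n_components components.

    Each observation is predicted exactly once, from a model fitted without
    its group; Q^2(a) = 1 - PRESS(a)/SS with SS about the full-data mean.
    """
    Xv, _, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = Xv.shape
    folds = _fold_assignment(n, groups, assignment_rule)
    a_max = int(n_components)
    preds = np.full((n, a_max), np.nan)
    for g in range(groups):
        test = folds == g
        train = ~test
        a_fit = min(a_max, int(train.sum()) - 1, p)
        sub = NipalsPLS(n_components=a_fit).fit(Xv[train], yv[train])
        for a in range(1, a_max + 1):
            preds[test, a - 1] = sub.predict(Xv[test], n_components=min(a, sub.n_components_))
    ss = float(np.sum((yv - yv.mean()) ** 2))
    press = np.sum((yv[:, None] - preds) ** 2, axis=0)
    return CVResult(fold_assignment=folds, press=press, q2=1.0 - press / ss)


def choose_components(X, y, max_a: int = 10, groups: int = 7,
                      threshold: float = 0.01,
                      assignment_rule: str = "venetian") -> tuple[int, CVResult]:
    """Add components while the incremental Q^2 gain exceeds ``threshold``.

    Always returns at least one component; a non-positive Q^2 at the chosen
    count signals an uninformative model and is left to the caller to flag.
    """
    Xv, _, _ = _as_matrix(X)
    n, p = Xv.shape
    a_cap = max(1, min(int(max_a), n - 1 - int(np.ceil(n / groups)), p))
    cv = q2_crossval(Xv, y, a_cap, groups=groups, assignment_rule=assignment_rule)
    chosen = 1
    while chosen < len(cv.q2) and cv.q2[chosen] - cv.q2[chosen - 1] > threshold:
        chosen += 1
    cv.chosen = chosen
    return chosen, cv


def vip(model: NipalsPLS) -> pd.Series:
    """Variable-importance-to-projection scores of a fitted PLS model.

    The squared scores average to one; descriptors with VIP > 1 contribute
    more than an average descriptor to the explained response variance.
    """
    W = model.x_weights_
    T = model.x_scores_
    q = model.y_loadings_
    p, A = W.shape
    ssy = q**2 * np.einsum("ia,ia->a", T, T)
    wnorm2 = np.sum(W**2, axis=0)
    contrib = (W**2 / wnorm2) @ ssy
    scores = np.sqrt(p * contrib / ssy.sum())
    return pd.Series(scores, index=model.feature_names_in_, name="VIP")
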