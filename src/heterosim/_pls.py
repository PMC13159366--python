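"""Partial least squares discriminant analysis (PLS2 / NIPALS) with VIP.

The discriminant response is the one-hot class-indicator matrix. Components
are extracted by NIPALS iteration (unit-norm X weights) with regression-mode
deflation of both X and Y by the X scores; the fit is deterministic given
the input order. VIP follows the standard definition

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )

with SSY_a the Y sum of squares explained by component a, which guarantees
mean(VIP^2) = 1 over the p features.
"""
from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold


class PLSDA(ClassifierMixin, BaseEstimator):
    """PLS-DA estimator (sklearn interface, X is samples x features).

    Attributes after fit: ``classes_``, ``x_weights_``, ``x_scores_``,
    ``x_loadings_``, ``y_loadings_`` (all with one column per component),
    ``explained_y_variance_`` (fraction of centered-Y sum of squares per
    component, non-increasing), ``vip_`` and, if ``cv`` is set, ``q2_``.
    """

    def __init__(self, n_components: int = 2, scale: bool = False,
                 max_iter: int = 500, tol: float = 1e-10, cv: int | None = None):
        self.n_components = n_components
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol
        self.cv = cv

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("PLS-DA needs at least 2 classes")
        Y = np.eye(len(self.classes_))[y_idx]
        n, p = X.shape
        if self.n_components > min(n - 1, p):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(n-1, p)={min(n - 1, p)}")
        self._x_mean = X.mean(axis=0)
        self._x_std = X.std(axis=0, ddof=1) if self.scale else np.ones(p)
        self._x_std = np.where(self._x_std == 0, 1.0, self._x_std)
        self._y_mean = Y.mean(axis=0)
        Xc = (X - self._x_mean) / self._x_std
        Yc = Y - self._y_mean
        self._nipals(Xc, Yc)
        self.vip_ = self._vip()
        if self.cv:
            self.q2_ = self._q2(X, y)
        return self

    def _nipals(self, X, Y):
        n, p = X.shape
        A = self.n_components
        W = np.zeros((p, A))
        T = np.zeros((n, A))
        P = np.zeros((p, A))
        Q = np.zeros((Y.shape[1], A))
        ssy_total = (Y ** 2).sum()
        ssy = np.zeros(A)
        Xr, Yr = X.copy(), Y.copy()
        for a in range(A):
            u = Yr[:, np.argmax((Yr ** 2).sum(axis=0))].copy()
            t_old = None
            for _ in range(self.max_iter):
                w = Xr.T @ u
                nw = np.linalg.norm(w)
                if nw == 0:
                    break
                w /= nw
                t = Xr @ w
                q = Yr.T @ t / (t @ t)
                u = Yr @ q / (q @ q)
                if t_old is not None and np.linalg.norm(t - t_old) < self.tol * np.linalg.norm(t):
                    break
                t_old = t
            tt = t @ t
            if tt == 0:
                # rank exhausted: truncate
                A = a
                W, T, P, Q, ssy = W[:, :a], T[:, :a], P[:, :a], Q[:, :a], ssy[:a]
                break
            p_load = Xr.T @ t / tt
            W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, p_load, q
            ssy[a] = tt * (q @ q)
            Xr = Xr - np.outer(t, p_load)
            Yr = Yr - np.outer(t, q)
        self.n_components_ = A
        self.x_weights_, self.x_scores_ = W, T
        self.x_loadings_, self.y_loadings_ = P, Q
        self.explained_y_variance_ = ssy / ssy_total if ssy_total > 0 else ssy
        self._ssy = ssy

    def _vip(self) -> np.ndarray:
        W, ssy = self.x_weights_, self._ssy
        p = W.shape[0]
        if ssy.sum() == 0:
            return np.ones(p)
        wnorm2 = (W ** 2).sum(axis=0)
        wnorm2 = np.where(wnorm2 == 0, 1.0, wnorm2)
        contrib = (W ** 2 / wnorm2) @ ssy
        return np.sqrt(p * contrib / ssy.sum())

    # -- prediction ---------------------------------------------------------

    def transform(self, X):
        Xc = (np.asarray(X, dtype=float) - self._x_mean) / self._x_std
        # scores via W(P'W)^-1 so deflation is accounted for
        R = self.x_weights_ @ np.linalg.inv(self.x_loadings_.T @ self.x_weights_)
        return Xc @ R

    def decision_function(self, X):
        R = self.x_weights_ @ np.linalg.inv(self.x_loadings_.T @ self.x_weights_)
        B = R @ self.y_loadings_.T
        Xc = (np.asarray(X, dtype=float) - self._x_mean) / self._x_std
        return Xc @ B + self._y_mean

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def _q2(self, X, y) -> float:
        """Cross-validated Q2 of the class-indicator prediction."""
        classes, y_idx = np.unique(y, return_inverse=True)
        Y = np.eye(len(classes))[y_idx]
        skf = StratifiedKFold(n_splits=self.cv, shuffle=False)
        press, ss = 0.0, 0.0
        for train, test in skf.split(X, y):
            sub = PLSDA(n_components=min(self.n_components,
                                         min(len(train) - 1, X.shape[1])),
                        scale=self.scale)
            sub.fit(X[train], y[train])
            Yhat = sub.decision_function(X[test])
            press += ((Y[test] - Yhat) ** 2).sum()
            ss += ((Y[test] - Y[train].mean(axis=0)) ** 2).sum()
        return 1.0 - press / ss if ss > 0 else np.nan
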