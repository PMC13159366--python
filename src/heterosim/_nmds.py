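"""Non-metric multidimensional scaling (Kruskal stress-1).

SMACOF-style optimizer: an isotonic-regression inner loop fits monotone
disparities to the configuration distances in the order of the input
dissimilarities, and a Guttman transform outer loop updates the
configuration. Restarts combine a classical (metric) MDS initialization
with seed-controlled random starts; the best (lowest-stress) accepted
solution is returned.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression
from sklearn.utils import check_random_state


def kruskal_stress(D: np.ndarray, X: np.ndarray) -> float:
    """Kruskal stress-1 of embedding X for dissimilarity matrix D.

    Disparities are the isotonic (primary tie treatment) regression of the
    configuration distances on the input dissimilarities;
    stress = sqrt(sum (d - dhat)^2 / sum d^2).
    """
    D = np.asarray(D, dtype=float)
    iu = np.triu_indices(D.shape[0], k=1)
    diss = D[iu]
    d = pdist(X)
    order = np.argsort(diss, kind="stable")
    iso = IsotonicRegression()
    dhat = np.empty_like(d)
    dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
    denom = (d ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[idx], 0, None)
    return vecs[:, idx] * np.sqrt(lam)


class NMDS(BaseEstimator):
    """Non-metric MDS estimator.

    Parameters
    ----------
    n_components : embedding dimension (k).
    n_restarts : number of starts (classical-MDS init plus random inits).
    max_iter, tol : outer-loop budget and relative stress-improvement
        threshold for convergence.
    random_state : seed for the random restarts.

    Attributes (after fit)
    ----------------------
    embedding_ : (n_samples, n_components) coordinates.
    stress_ : final Kruskal stress-1.
    converged_ : True if any restart converged within max_iter.
    n_restarts_used_ : restarts actually run.
    """

    def __init__(self, n_components: int = 2, n_restarts: int = 4,
                 max_iter: int = 300, tol: float = 1e-7, random_state=None):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, D, y=None):
        D = np.asarray(D, dtype=float)
        n = D.shape[0]
        if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
            raise ValueError("NMDS expects a square symmetric dissimilarity matrix")
        if n < self.n_components + 2:
            raise ValueError("need at least n_components + 2 samples")
        rng = check_random_state(self.random_state)
        iu = np.triu_indices(n, k=1)
        diss = D[iu]
        order = np.argsort(diss, kind="stable")

        best = None
        converged_any = False
        for r in range(self.n_restarts):
            if r == 0:
                X = _classical_mds(D, self.n_components)
            else:
                X = rng.normal(size=(n, self.n_components)) * diss.mean()
            X, stress, conv = self._optimize(X, order, iu, n)
            converged_any = converged_any or conv
            if best is None or stress < best[1]:
                best = (X, stress)
        self.embedding_, self.stress_ = best
        self.converged_ = converged_any
        self.n_restarts_used_ = self.n_restarts
        return self

    def fit_transform(self, D, y=None):
        return self.fit(D).embedding_

    def _optimize(self, X, order, iu, n):
        iso = IsotonicRegression()
        seq = np.arange(len(order), dtype=float)
        prev = np.inf
        converged = False
        stress = np.inf
        for _ in range(self.max_iter):
            d = pdist(X)
            dhat = np.empty_like(d)
            dhat[order] = iso.fit_transform(seq, d[order])
            denom = (d ** 2).sum()
            if denom == 0:
                stress = 0.0
                converged = True
                break
            stress = float(np.sqrt(((d - dhat) ** 2).sum() / denom))
            if prev - stress < self.tol * max(prev, 1e-12):
                converged = True
                break
            prev = stress
            # Guttman transform with ratios dhat/d (zero-distance pairs -> 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            R = squareform(ratio)
            B = -R
            np.fill_diagonal(B, R.sum(axis=1))
            X = (B @ X) / n
            X = X - X.mean(axis=0)
        return X, stress, converged
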