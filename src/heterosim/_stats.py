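"""Vectorized statistical kernels shared across modules.

Everything here operates on features x samples arrays so that whole omics
layers can be tested in one call; the public per-feature functions in
`heterosis` and the network builders in `community`/`integration` are thin
wrappers over these.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney U)
# ---------------------------------------------------------------------------

def ranksum_rows(X1: np.ndarray, X2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-sided Wilcoxon rank-sum test applied row-wise.

    Normal approximation with average-rank tie handling and continuity
    correction. Rows where the pooled values are all identical get p = 1 and
    direction 0. Returns (statistic U, p, direction sign of mean difference).
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(X1, X2, axis=1, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        stat = np.atleast_1d(np.asarray(res.statistic, dtype=float))
        p = np.atleast_1d(np.asarray(res.pvalue, dtype=float))
    pooled = np.concatenate([X1, X2], axis=1)
    degenerate = np.all(pooled == pooled[:, :1], axis=1)
    p = np.where(degenerate, 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    direction = np.sign(X1.mean(axis=1) - X2.mean(axis=1))
    direction = np.where(degenerate, 0.0, direction)
    return stat, p, direction


def ranksum_exact_or_asymptotic(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Single-pair rank-sum test.

    Exact null enumeration when both groups have <= 25 observations and the
    pooled data has no ties; otherwise the tie-corrected normal approximation
    with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0, 0.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(x) <= 25 and len(y) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue), float(np.sign(x.mean() - y.mean()))


# ---------------------------------------------------------------------------
# Welch tests
# ---------------------------------------------------------------------------

def welch_rows(X1: np.ndarray, X2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch two-sample t test (two-sided)."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(X1, X2, axis=1, equal_var=False)
    t = np.atleast_1d(np.asarray(res.statistic, dtype=float))
    p = np.atleast_1d(np.asarray(res.pvalue, dtype=float))
    degenerate = np.isnan(p)
    p = np.where(degenerate, 1.0, p)
    direction = np.sign(X1.mean(axis=1) - X2.mean(axis=1))
    direction = np.where(degenerate & (direction == 0), 0.0, direction)
    return t, p, direction


def midparent_contrast_rows(XP1: np.ndarray, XF1: np.ndarray, XP2: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Welch-style mid-parent contrast, row-wise.

    t = (mean_F1 - (mean_P1 + mean_P2)/2) / se with
    se^2 = s2_F1/n_F1 + s2_P1/(4 n_P1) + s2_P2/(4 n_P2) and Satterthwaite
    degrees of freedom. Returns (t, df, p). Rows with zero pooled variance
    yield t = nan, p = nan.
    """
    XP1 = np.atleast_2d(np.asarray(XP1, dtype=float))
    XF1 = np.atleast_2d(np.asarray(XF1, dtype=float))
    XP2 = np.atleast_2d(np.asarray(XP2, dtype=float))
    n1, nf, n2 = XP1.shape[1], XF1.shape[1], XP2.shape[1]
    m1, mf, m2 = XP1.mean(axis=1), XF1.mean(axis=1), XP2.mean(axis=1)
    v1 = XP1.var(axis=1, ddof=1)
    vf = XF1.var(axis=1, ddof=1)
    v2 = XP2.var(axis=1, ddof=1)
    a = vf / nf
    b = v1 / (4.0 * n1)
    c = v2 / (4.0 * n2)
    se2 = a + b + c
    contrast = mf - (m1 + m2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = contrast / np.sqrt(se2)
        df = se2 ** 2 / (a ** 2 / (nf - 1) + b ** 2 / (n1 - 1) + c ** 2 / (n2 - 1))
    zero_contrast = (se2 > 0) & (contrast == 0)
    t = np.where(zero_contrast, 0.0, t)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero_contrast, 1.0, p)
    bad = se2 == 0
    t = np.where(bad, np.nan, t)
    df = np.where(bad, np.nan, df)
    p = np.where(bad, np.nan, p)
    return t, df, p


def midparent_permutation_rows(XP1, XF1, XP2, n_perm: int, rng: np.random.Generator
                               ) -> np.ndarray:
    """Group-label permutation p-value for the mid-parent contrast, row-wise.

    Permutes sample-to-group assignments (preserving group sizes) and
    recomputes the raw contrast mean_F1 - mid-parent; two-sided p with the
    +1 correction so p is never exactly 0.
    """
    XP1 = np.atleast_2d(np.asarray(XP1, dtype=float))
    XF1 = np.atleast_2d(np.asarray(XF1, dtype=float))
    XP2 = np.atleast_2d(np.asarray(XP2, dtype=float))
    X = np.concatenate([XP1, XF1, XP2], axis=1)
    n1, nf = XP1.shape[1], XF1.shape[1]
    n = X.shape[1]
    obs = XF1.mean(axis=1) - (XP1.mean(axis=1) + XP2.mean(axis=1)) / 2.0
    exceed = np.zeros(X.shape[0], dtype=int)
    for _ in range(n_perm):
        idx = rng.permutation(n)
        Xp = X[:, idx]
        stat = Xp[:, n1:n1 + nf].mean(axis=1) - (
            Xp[:, :n1].mean(axis=1) + Xp[:, n1 + nf:].mean(axis=1)) / 2.0
        exceed += np.abs(stat) >= np.abs(obs) - 1e-12
    return (exceed + 1.0) / (n_perm + 1.0)


# ---------------------------------------------------------------------------
# Spearman correlation, all pairs at once
# ---------------------------------------------------------------------------

def _rank_standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row ranks (average ties), centered; returns (R, row L2 norms)."""
    R = stats.rankdata(np.asarray(X, dtype=float), axis=1)
    R = R - R.mean(axis=1, keepdims=True)
    norms = np.sqrt((R ** 2).sum(axis=1))
    return R, norms


def spearman_rows(A: np.ndarray, B: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p for every row pair of A (x B).

    Matches scipy.stats.spearmanr (t-distribution approximation, average-rank
    ties). Constant rows give nan rho/p; callers skip those pairs.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    n = A.shape[1]
    Ra, na = _rank_standardize(A)
    if B is None:
        Rb, nb = Ra, na
    else:
        B = np.atleast_2d(np.asarray(B, dtype=float))
        if B.shape[1] != n:
            raise ValueError("A and B must have the same number of samples")
        Rb, nb = _rank_standardize(B)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (Ra @ Rb.T) / np.outer(na, nb)
    rho = np.clip(rho, -1.0, 1.0)
    p = spearman_pvalues(rho, n)
    return rho, p


def spearman_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p via the t approximation used by scipy.stats.spearmanr."""
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    p = np.where(np.isnan(rho), np.nan, p)
    return p
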