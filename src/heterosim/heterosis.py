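"""Mid-parent heterosis statistics and additive/dominance/overdominance
pattern classification for a two-parent + F1 crossbreeding design.

The heterosis rate of a feature (genus relative abundance, log10 metabolite
content, normalized gene expression) is the percent deviation of the hybrid
mean from the mid-parent value MP = (mean_P1 + mean_P2)/2:

    H% = 100 * (mean_F1 - MP) / |MP|

Significance of the deviation is assessed with a Welch-style contrast t
statistic with Satterthwaite degrees of freedom (a seed-controlled
group-label permutation test is available as an alternative).

Each feature is further classified into one of 12 abundance-pattern types
grouped into three categories by three pairwise two-group tests
(P1 vs P2, F1 vs P1, F1 vs P2):

* additive (types I, XII): the parents differ significantly and the hybrid
  sits between them;
* dominance (types II, IV, IX, XI): the hybrid differs significantly from
  exactly one parent (reported as abundance level up/down relative to the
  mid-parent);
* overdominance (types III, V, VI, VII, VIII, X): the hybrid is
  significantly above both parents (transgressive high) or below both
  (transgressive low).

A feature is called *nonadditive* when it deviates significantly from the
mid-parent expectation and falls in a dominance or overdominance pattern.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _stats
from .design import COMPARISONS, GROUPS, split_by_group

CATEGORIES = ("additive", "dominance", "overdominance", "unclassified")
SUBCATEGORIES = ("level_up", "level_down", "transgressive_high", "transgressive_low", "none")


@dataclass
class HeterosisResult:
    """Mid-parent heterosis outcome for one feature."""
    feature_id: str
    mid_parent: float
    H_pct: float
    t_stat: float
    df: float
    p_value: float
    direction: str  # positive / negative / none


@dataclass
class PairwiseTestResult:
    comparison: str  # P1vP2, F1vP1 or F1vP2
    statistic: float
    p_value: float
    direction: int  # sign of (first-listed group's mean - second's)


@dataclass
class PatternCall:
    feature_id: str
    type_roman: str  # I..XII or "unclassified"
    category: str
    subcategory: str


def group_summary(X: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-group n, mean and variance (ddof=1) for each feature row."""
    parts = split_by_group(X, design)
    out = {}
    for g in GROUPS:
        block = parts[g].to_numpy(dtype=float)
        out[(g, "n")] = np.full(X.shape[0], block.shape[1])
        out[(g, "mean")] = block.mean(axis=1)
        out[(g, "var")] = block.var(axis=1, ddof=1)
    df = pd.DataFrame(out, index=X.index)
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return df


# ---------------------------------------------------------------------------
# Mid-parent heterosis
# ---------------------------------------------------------------------------

def mid_parent_heterosis(values_P1, values_F1, values_P2, alpha: float = 0.05,
                         method: str = "welch", n_perm: int = 999,
                         seed: int | None = None,
                         feature_id: str = "feature") -> HeterosisResult:
    """Heterosis rate H% of one feature with its mid-parent deviation test.

    Raises if any group has n < 3, if the pooled variance is zero
    ("degenerate input"), or if the mid-parent value is exactly zero
    ("undefined heterosis rate").
    """
    arrs = [np.asarray(v, dtype=float) for v in (values_P1, values_F1, values_P2)]
    if min(a.size for a in arrs) < 3:
        raise ValueError("each group needs at least 3 observations")
    design = _inline_design(*[a.size for a in arrs])
    table = heterosis_table(
        pd.DataFrame([np.concatenate(arrs)], index=[feature_id],
                     columns=design["sample_id"].tolist()),
        design,
        alpha=alpha, method=method, n_perm=n_perm, seed=seed,
    )
    row = table.iloc[0]
    if np.isnan(row["p_value"]):
        raise ValueError("degenerate input: zero pooled variance across all groups")
    if np.isnan(row["H_pct"]):
        raise ValueError("undefined heterosis rate: mid-parent value is zero")
    return HeterosisResult(feature_id, row["mid_parent"], row["H_pct"],
                           row["t_stat"], row["df"], row["p_value"], row["direction"])


def _inline_design(n1: int, nf: int, n2: int) -> pd.DataFrame:
    ids = [f"s{i}" for i in range(n1 + nf + n2)]
    groups = ["P1"] * n1 + ["F1"] * nf + ["P2"] * n2
    return pd.DataFrame({"sample_id": ids, "group": groups})


def heterosis_table(X: pd.DataFrame, design: pd.DataFrame, alpha: float = 0.05,
                    method: str = "welch", n_perm: int = 999,
                    seed: int | None = None) -> pd.DataFrame:
    """Vectorized H% and mid-parent deviation test for every feature row of X.

    Columns: mid_parent, H_pct, t_stat, df, p_value, direction. Features with
    MP = 0 get H_pct = nan; features with zero pooled variance get p = nan.
    """
    parts = split_by_group(X, design)
    P1 = parts["P1"].to_numpy(dtype=float)
    F1 = parts["F1"].to_numpy(dtype=float)
    P2 = parts["P2"].to_numpy(dtype=float)
    mp = (P1.mean(axis=1) + P2.mean(axis=1)) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        h = 100.0 * (F1.mean(axis=1) - mp) / np.abs(mp)
    h = np.where(mp == 0, np.nan, h)
    t, df, p = _stats.midparent_contrast_rows(P1, F1, P2)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        p = _stats.midparent_permutation_rows(P1, F1, P2, n_perm, rng)
        p = np.where(np.isnan(t), np.nan, p)
    elif method != "welch":
        raise ValueError(f"unknown method {method!r}; use 'welch' or 'permutation'")
    sig = p < alpha
    direction = np.where(sig & (h > 0), "positive",
                         np.where(sig & (h < 0), "negative", "none"))
    return pd.DataFrame({
        "mid_parent": mp, "H_pct": h, "t_stat": t, "df": df,
        "p_value": p, "direction": direction,
    }, index=X.index)


# ---------------------------------------------------------------------------
# Pairwise tests
# ---------------------------------------------------------------------------

def pairwise_tests(values_by_group: dict, test: str = "wilcoxon") -> list[PairwiseTestResult]:
    """The three pairwise two-group tests for one feature.

    ``test`` is ``"wilcoxon"`` (rank-sum; exact enumeration when both groups
    have <= 25 untied observations, tie-corrected normal approximation with
    continuity correction otherwise) or ``"welch"``.
    """
    out = []
    for name, ga, gb in COMPARISONS:
        a = np.asarray(values_by_group[ga], dtype=float)
        b = np.asarray(values_by_group[gb], dtype=float)
        if a.size < 3 or b.size < 3:
            raise ValueError("each group needs at least 3 observations")
        if test == "wilcoxon":
            stat, p, d = _stats.ranksum_exact_or_asymptotic(a, b)
        elif test == "welch":
            t, parr, darr = _stats.welch_rows(a[None, :], b[None, :])
            stat, p, d = float(t[0]), float(parr[0]), float(darr[0])
        else:
            raise ValueError(f"unknown test {test!r}; use 'wilcoxon' or 'welch'")
        out.append(PairwiseTestResult(name, stat, p, int(d)))
    return out


def pairwise_tables(X: pd.DataFrame, design: pd.DataFrame, test: str = "wilcoxon"
                    ) -> dict[str, pd.DataFrame]:
    """Vectorized pairwise tests for all features; one table per comparison."""
    parts = {g: df.to_numpy(dtype=float) for g, df in split_by_group(X, design).items()}
    row_test = _stats.ranksum_rows if test == "wilcoxon" else _stats.welch_rows
    if test not in ("wilcoxon", "welch"):
        raise ValueError(f"unknown test {test!r}")
    out = {}
    for name, ga, gb in COMPARISONS:
        stat, p, d = row_test(parts[ga], parts[gb])
        out[name] = pd.DataFrame({"statistic": stat, "p_value": p, "direction": d},
                                 index=X.index)
    return out


# ---------------------------------------------------------------------------
# Pattern classification
# ---------------------------------------------------------------------------

def classify_pattern(tests: list[PairwiseTestResult], means: dict, alpha: float = 0.05,
                     feature_id: str = "feature") -> PatternCall:
    """Classify one feature from its three pairwise tests and group means."""
    by = {t.comparison: t for t in tests}
    table = _classify_arrays(
        sig12=np.array([by["P1vP2"].p_value < alpha]),
        d12=np.array([float(by["P1vP2"].direction)]),
        sigF1=np.array([by["F1vP1"].p_value < alpha]),
        dF1=np.array([float(by["F1vP1"].direction)]),
        sigF2=np.array([by["F1vP2"].p_value < alpha]),
        dF2=np.array([float(by["F1vP2"].direction)]),
        mP1=np.array([float(means["P1"])]),
        mF1=np.array([float(means["F1"])]),
        mP2=np.array([float(means["P2"])]),
    )
    return PatternCall(feature_id, table["type_roman"][0],
                       table["category"][0], table["subcategory"][0])


def classify_patterns(X: pd.DataFrame, design: pd.DataFrame, alpha: float = 0.05,
                      test: str = "wilcoxon") -> pd.DataFrame:
    """Pattern calls for every feature row of X.

    Returns a DataFrame with the three pairwise p-values/directions and the
    assigned type_roman, category and subcategory.
    """
    tables = pairwise_tables(X, design, test=test)
    parts = split_by_group(X, design)
    means = {g: parts[g].to_numpy(dtype=float).mean(axis=1) for g in GROUPS}
    res = _classify_arrays(
        sig12=tables["P1vP2"]["p_value"].to_numpy() < alpha,
        d12=tables["P1vP2"]["direction"].to_numpy(),
        sigF1=tables["F1vP1"]["p_value"].to_numpy() < alpha,
        dF1=tables["F1vP1"]["direction"].to_numpy(),
        sigF2=tables["F1vP2"]["p_value"].to_numpy() < alpha,
        dF2=tables["F1vP2"]["direction"].to_numpy(),
        mP1=means["P1"], mF1=means["F1"], mP2=means["P2"],
    )
    out = pd.DataFrame(index=X.index)
    for name in ("P1vP2", "F1vP1", "F1vP2"):
        out[f"p_{name}"] = tables[name]["p_value"].to_numpy()
        out[f"dir_{name}"] = tables[name]["direction"].to_numpy().astype(int)
    out["type_roman"] = res["type_roman"]
    out["category"] = res["category"]
    out["subcategory"] = res["subcategory"]
    return out


def _classify_arrays(sig12, d12, sigF1, dF1, sigF2, dF2, mP1, mF1, mP2) -> dict:
    """Decision table over the three (significance, sign) test outcomes.

    Total: every outcome combination maps to exactly one of the four
    categories. Mutual exclusivity is by construction: overdominance takes
    both F1-vs-parent tests significant in the same direction, additivity
    takes both significant in opposite directions (or neither significant)
    with significantly different parents and an intermediate hybrid, and
    dominance takes exactly one significant.
    """
    mp = (mP1 + mP2) / 2.0
    over = sigF1 & sigF2 & (dF1 == dF2) & (dF1 != 0)
    dom = (sigF1 ^ sigF2)
    between = (mF1 >= np.minimum(mP1, mP2)) & (mF1 <= np.maximum(mP1, mP2))
    opposite = sigF1 & sigF2 & (dF1 == -dF2) & (dF1 != 0)
    neither = ~sigF1 & ~sigF2
    add = ~over & ~dom & sig12 & between & (opposite | neither)

    n = len(mp)
    category = np.full(n, "unclassified", dtype=object)
    subcategory = np.full(n, "none", dtype=object)
    roman = np.full(n, "unclassified", dtype=object)

    category[add] = "additive"
    roman[add & (d12 > 0)] = "I"
    roman[add & (d12 <= 0)] = "XII"

    level_up = mF1 > mp
    category[dom] = "dominance"
    subcategory[dom & level_up] = "level_up"
    subcategory[dom & ~level_up] = "level_down"
    # numeral by which parent the hybrid matches (the non-significant test)
    match_p1 = dom & ~sigF1
    match_p2 = dom & sigF1
    roman[match_p1 & level_up] = "II"
    roman[match_p1 & ~level_up] = "XI"
    roman[match_p2 & level_up] = "IV"
    roman[match_p2 & ~level_up] = "IX"

    category[over] = "overdominance"
    high = over & (dF1 > 0)
    low = over & (dF1 < 0)
    subcategory[high] = "transgressive_high"
    subcategory[low] = "transgressive_low"
    roman[high & (d12 > 0)] = "III"
    roman[high & (d12 == 0)] = "V"
    roman[high & (d12 < 0)] = "VI"
    roman[low & (d12 > 0)] = "VII"
    roman[low & (d12 == 0)] = "VIII"
    roman[low & (d12 < 0)] = "X"

    return {"category": category, "subcategory": subcategory, "type_roman": roman}


# ---------------------------------------------------------------------------
# Summaries and the nonadditive call
# ---------------------------------------------------------------------------

def summarize_patterns(calls: pd.DataFrame | list) -> dict:
    """Counts and percentages per category and subcategory.

    Percentages are over classified features; the unclassified fraction is
    reported separately. Accepts the DataFrame from classify_patterns or a
    list of PatternCall.
    """
    if isinstance(calls, list):
        if not calls:
            raise ValueError("no pattern calls to summarize")
        calls = pd.DataFrame({
            "category": [c.category for c in calls],
            "subcategory": [c.subcategory for c in calls],
        })
    if calls.empty:
        raise ValueError("no pattern calls to summarize")
    total = len(calls)
    classified = calls[calls["category"] != "unclassified"]
    n_class = len(classified)
    cat_counts = {c: int((classified["category"] == c).sum())
                  for c in ("additive", "dominance", "overdominance")}
    cat_pct = {c: (100.0 * v / n_class if n_class else 0.0) for c, v in cat_counts.items()}
    sub_counts = {s: int((classified["subcategory"] == s).sum())
                  for s in ("level_up", "level_down", "transgressive_high", "transgressive_low")}
    return {
        "n_total": total,
        "n_classified": n_class,
        "n_unclassified": total - n_class,
        "category_counts": cat_counts,
        "category_pct": cat_pct,
        "subcategory_counts": sub_counts,
    }


def heterosis_analysis(X: pd.DataFrame, design: pd.DataFrame, alpha: float = 0.05,
                       test: str = "wilcoxon", method: str = "welch",
                       seed: int | None = None) -> pd.DataFrame:
    """Full per-feature table: H%, mid-parent test, pattern call, nonadditive flag.

    ``nonadditive`` is True when the feature deviates significantly from the
    mid-parent expectation (p < alpha) and its pattern category is dominance
    or overdominance.
    """
    het = heterosis_table(X, design, alpha=alpha, method=method, seed=seed)
    pat = classify_patterns(X, design, alpha=alpha, test=test)
    out = het.join(pat)
    out["nonadditive"] = (out["p_value"] < alpha) & out["category"].isin(
        ["dominance", "overdominance"])
    return out
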