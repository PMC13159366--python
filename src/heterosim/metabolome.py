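"""Metabolite-matrix preprocessing and differential analysis.

Fixed, auditable pipeline order: annotation-level filter -> group-wise
missingness filter -> half-minimum imputation -> log10 transform ->
autoscaling -> PLS-DA / VIP -> VIP-gated differential calling -> origin
partitioning. Missingness is distinguished from observed zero in the input
(NaN = missing, 0 = observed zero), matching LC-MS detection semantics.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import _stats
from ._pls import PLSDA
from .design import COMPARISONS, split_by_group

ORIGIN_CLASSES = ("host", "microbiota", "co_metabolism", "other")


# ---------------------------------------------------------------------------
# Estimators (samples x features)
# ---------------------------------------------------------------------------

class HalfMinimumImputer(TransformerMixin, BaseEstimator):
    """Replace missing (NaN) cells by half the minimum non-zero intensity
    across the whole matrix seen at fit time. Observed cells are untouched."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        observed = X[~np.isnan(X)]
        positive = observed[observed > 0]
        if positive.size == 0:
            raise ValueError("no non-missing positive intensity to derive the imputation value")
        self.fill_value_ = 0.5 * positive.min()
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float).copy()
        X[np.isnan(X)] = self.fill_value_
        return X


class Log10Autoscaler(TransformerMixin, BaseEstimator):
    """log10 then per-feature autoscaling (mean 0, unit SD) or Pareto scaling.

    Zero-variance features are dropped (``support_`` records the kept ones).
    """

    def __init__(self, scaling: str = "unit"):
        self.scaling = scaling

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if (X <= 0).any() or np.isnan(X).any():
            raise ValueError("log10 scaling requires strictly positive, fully observed intensities")
        L = np.log10(X)
        self.mean_ = L.mean(axis=0)
        sd = L.std(axis=0)  # population SD: unit-variance rows after scaling
        # tolerance relative to the feature mean: a constant feature can show
        # sd ~ 1e-16 from rounding alone, which must not pass as variance
        self.support_ = sd > 1e-12 * np.maximum(1.0, np.abs(self.mean_))
        if (~self.support_).any():
            warnings.warn(f"dropping {int((~self.support_).sum())} zero-variance feature(s)")
        if self.scaling == "unit":
            self.scale_ = sd
        elif self.scaling == "pareto":
            self.scale_ = np.sqrt(sd)
        else:
            raise ValueError(f"unknown scaling {self.scaling!r}")
        return self

    def transform(self, X):
        L = np.log10(np.asarray(X, dtype=float))
        out = (L - self.mean_) / np.where(self.scale_ == 0, 1.0, self.scale_)
        return out[:, self.support_]


# ---------------------------------------------------------------------------
# Annotation handling
# ---------------------------------------------------------------------------

def annotation_level_filter(annotations: pd.DataFrame) -> pd.DataFrame:
    """Assign annotation confidence levels and keep levels 1 and 2.

    Level 1: |rt_error| <= 0.3 min and fragmentation_score >= 45;
    level 2: |rt_error| <= 0.3 min and fragmentation_score < 45;
    everything else (including rows with missing fields) is dropped.
    Returns the retained rows with a ``level`` column.
    """
    ann = annotations.copy()
    required = {"metabolite_id", "rt_error", "fragmentation_score"}
    missing_cols = required - set(ann.columns)
    if missing_cols:
        raise ValueError(f"annotation table lacks columns: {sorted(missing_cols)}")
    bad = ann["rt_error"].isna() | ann["fragmentation_score"].isna()
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} metabolite(s) with missing annotation fields")
        ann = ann[~bad]
    in_rt = ann["rt_error"].abs() <= 0.3
    level = np.where(~in_rt, 0, np.where(ann["fragmentation_score"] >= 45, 1, 2))
    ann = ann.assign(level=level)
    return ann[ann["level"] > 0]


# ---------------------------------------------------------------------------
# Matrix preprocessing (features x samples)
# ---------------------------------------------------------------------------

def filter_missingness(intensities: pd.DataFrame, design: pd.DataFrame,
                       max_frac: float = 0.5) -> pd.DataFrame:
    """Drop a metabolite if its missing fraction strictly exceeds
    ``max_frac`` within any one group."""
    drop = np.zeros(intensities.shape[0], dtype=bool)
    for block in split_by_group(intensities, design).values():
        drop |= block.isna().mean(axis=1).to_numpy() > max_frac
    return intensities.loc[~drop]


def impute_half_min(intensities: pd.DataFrame) -> pd.DataFrame:
    """Half-minimum imputation: every missing cell becomes 0.5 x the global
    minimum non-zero intensity (one value for the whole dataset)."""
    imp = HalfMinimumImputer().fit(intensities.T.to_numpy(dtype=float))
    out = imp.transform(intensities.T.to_numpy(dtype=float)).T
    return pd.DataFrame(out, index=intensities.index, columns=intensities.columns)


def log10_autoscale(intensities: pd.DataFrame, scaling: str = "unit") -> pd.DataFrame:
    """log10 + per-feature autoscaling; zero-variance features are dropped."""
    sc = Log10Autoscaler(scaling=scaling).fit(intensities.T.to_numpy(dtype=float))
    out = sc.transform(intensities.T.to_numpy(dtype=float)).T
    return pd.DataFrame(out, index=intensities.index[sc.support_],
                        columns=intensities.columns)


# ---------------------------------------------------------------------------
# PLS-DA / VIP / differential calling
# ---------------------------------------------------------------------------

def plsda_fit(X: pd.DataFrame, design: pd.DataFrame, n_components: int = 2,
              cv: int | None = 5) -> PLSDA:
    """Fit PLS-DA on a features x samples matrix against the group labels."""
    groups = _labels(design, X.columns)
    model = PLSDA(n_components=n_components, cv=cv)
    model.fit(X.T.to_numpy(dtype=float), groups)
    return model


def vip_scores(model: PLSDA, feature_ids) -> pd.Series:
    """Per-feature VIP of a fitted PLS-DA model."""
    return pd.Series(model.vip_, index=feature_ids, name="vip")


def _labels(design: pd.DataFrame, sample_ids) -> np.ndarray:
    from .design import group_masks
    masks = group_masks(design, sample_ids)
    labels = np.empty(len(sample_ids), dtype=object)
    for g, m in masks.items():
        labels[m] = g
    return labels.astype(str)


@dataclass
class DifferentialCall:
    metabolite_id: str
    comparison: str
    direction: str  # up / down in the first-listed group
    vip: float
    p_value: float


def differential_metabolites(X: pd.DataFrame, design: pd.DataFrame,
                             vip_threshold: float = 1.0, alpha: float = 0.05,
                             test: str = "wilcoxon", n_components: int = 2
                             ) -> pd.DataFrame:
    """VIP-gated differential calling per pairwise comparison.

    For each comparison a two-class PLS-DA provides the VIPs; a metabolite is
    called iff VIP > vip_threshold (strict) and the two-group test p < alpha.
    Returns the full per-comparison table with a ``called`` flag.
    """
    parts = split_by_group(X, design)
    rows = []
    for name, ga, gb in COMPARISONS:
        A = parts[ga].to_numpy(dtype=float)
        B = parts[gb].to_numpy(dtype=float)
        Xp = np.concatenate([A, B], axis=1).T
        y = np.array([ga] * A.shape[1] + [gb] * B.shape[1])
        nc = min(n_components, Xp.shape[0] - 1, Xp.shape[1])
        model = PLSDA(n_components=nc).fit(Xp, y)
        if test == "wilcoxon":
            _, p, d = _stats.ranksum_rows(A, B)
        elif test == "welch":
            _, p, d = _stats.welch_rows(A, B)
        else:
            raise ValueError(f"unknown test {test!r}")
        vip = model.vip_
        called = (vip > vip_threshold) & (p < alpha)
        rows.append(pd.DataFrame({
            "metabolite_id": X.index.astype(str),
            "comparison": name,
            "vip": vip,
            "p_value": p,
            "direction": np.where(d > 0, "up", np.where(d < 0, "down", "none")),
            "called": called,
        }))
    return pd.concat(rows, ignore_index=True)


def differential_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts of called / up / down metabolites per comparison."""
    out = []
    for name, block in calls.groupby("comparison"):
        called = block[block["called"]]
        out.append({"comparison": name, "n_called": len(called),
                    "n_up": int((called["direction"] == "up").sum()),
                    "n_down": int((called["direction"] == "down").sum())})
    return pd.DataFrame(out).set_index("comparison")


# ---------------------------------------------------------------------------
# Origin partition
# ---------------------------------------------------------------------------

def source_partition(metabolite_ids, annotations: pd.DataFrame) -> dict:
    """Partition metabolites by biological origin class.

    ``origin`` may be a single class or several separated by '|'
    (co_metabolism counts toward both host and microbiota). Returns class
    counts, the host/microbiota overlap, and ids with unknown origin.
    """
    ann = annotations.set_index(annotations["metabolite_id"].astype(str))
    host, microbe, other, unknown = set(), set(), set(), set()
    for mid in map(str, metabolite_ids):
        if mid not in ann.index:
            unknown.add(mid)
            continue
        origins = {o.strip() for o in str(ann.loc[mid, "origin"]).split("|")}
        hit = False
        if origins & {"host", "co_metabolism"}:
            host.add(mid)
            hit = True
        if origins & {"microbiota", "co_metabolism"}:
            microbe.add(mid)
            hit = True
        if "other" in origins:
            other.add(mid)
            hit = True
        if not hit:
            unknown.add(mid)
    return {
        "host": sorted(host),
        "microbiota": sorted(microbe),
        "overlap": sorted(host & microbe),
        "other": sorted(other),
        "unknown": sorted(unknown),
        "counts": {"host": len(host), "microbiota": len(microbe),
                   "overlap": len(host & microbe), "other": len(other),
                   "unknown": len(unknown)},
    }


# ---------------------------------------------------------------------------
# End-to-end preprocessing
# ---------------------------------------------------------------------------

def preprocess(intensities: pd.DataFrame, design: pd.DataFrame,
               annotations: pd.DataFrame | None = None, max_missing: float = 0.5,
               scaling: str = "unit") -> tuple[pd.DataFrame, dict]:
    """Run the full preprocessing chain and log features in/out per stage.

    Returns (processed matrix on the log10-autoscaled analysis scale, audit
    dict of per-stage feature counts).
    """
    audit = {"input": int(intensities.shape[0])}
    X = intensities
    if annotations is not None:
        keep = annotation_level_filter(annotations)["metabolite_id"].astype(str)
        X = X.loc[X.index.astype(str).isin(set(keep))]
    audit["after_level_filter"] = int(X.shape[0])
    X = filter_missingness(X, design, max_frac=max_missing)
    audit["after_missingness_filter"] = int(X.shape[0])
    X = impute_half_min(X)
    audit["after_imputation"] = int(X.shape[0])
    X = log10_autoscale(X, scaling=scaling)
    audit["after_log10_autoscale"] = int(X.shape[0])
    return X, audit
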