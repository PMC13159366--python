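"""Three-group crossbreeding design: two parental lines (P1, P2) and their F1 progeny.

Group labels are generic so the machinery is line-agnostic; the broiler
study aliases are CC (paternal Cornish line, P1), CR (crossbred progeny,
F1) and RR (maternal White Plymouth Rock line, P2).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

GROUPS = ("P1", "F1", "P2")

GROUP_ALIASES = {"P1": "CC", "F1": "CR", "P2": "RR"}
ALIAS_TO_GROUP = {v: k for k, v in GROUP_ALIASES.items()}

#: pairwise comparisons used throughout: (name, first group, second group).
#: Direction is always the sign of (mean of first) - (mean of second).
COMPARISONS = (("P1vP2", "P1", "P2"), ("F1vP1", "F1", "P1"), ("F1vP2", "F1", "P2"))


def validate_design(design: pd.DataFrame, min_per_group: int = 1) -> pd.DataFrame:
    """Check a design table (columns sample_id, group) and return it normalized.

    Accepts either generic labels (P1/F1/P2) or the display aliases
    (CC/CR/RR) in the ``group`` column; aliases are mapped to generic labels.
    """
    if not {"sample_id", "group"}.issubset(design.columns):
        raise ValueError("design must have columns 'sample_id' and 'group'")
    design = design.copy()
    design["sample_id"] = design["sample_id"].astype(str)
    design["group"] = design["group"].astype(str).map(lambda g: ALIAS_TO_GROUP.get(g, g))
    bad = sorted(set(design["group"]) - set(GROUPS))
    if bad:
        raise ValueError(f"unknown group labels: {bad}; expected {GROUPS} or aliases {tuple(GROUP_ALIASES.values())}")
    if design["sample_id"].duplicated().any():
        dups = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in design: {dups}")
    counts = design["group"].value_counts()
    for g in GROUPS:
        if counts.get(g, 0) < min_per_group:
            raise ValueError(f"group {g} has {counts.get(g, 0)} samples; at least {min_per_group} required")
    return design


def group_masks(design: pd.DataFrame, sample_ids) -> dict[str, np.ndarray]:
    """Boolean mask per group, aligned to ``sample_ids`` order."""
    design = validate_design(design)
    lookup = dict(zip(design["sample_id"], design["group"]))
    missing = [s for s in sample_ids if str(s) not in lookup]
    if missing:
        raise ValueError(f"samples absent from design: {missing[:5]}")
    labels = np.array([lookup[str(s)] for s in sample_ids])
    return {g: labels == g for g in GROUPS}


def split_by_group(X: pd.DataFrame, design: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a features x samples table into one sub-table per group."""
    masks = group_masks(design, X.columns)
    return {g: X.loc[:, m] for g, m in masks.items()}
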