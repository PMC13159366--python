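"""TSV input/output for all tables.

Conventions: feature x sample matrices with features as rows and a header
row of sample ids; empty cells (or NA/NaN) mean *missing* and are only
legal in the metabolome layer; the design table has columns sample_id and
group; taxonomy, annotation and pathway sidecars are plain TSV.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import validate_design

LAYERS = ("microbiome", "metabolome", "transcriptome", "generic")


def read_matrix(path, layer: str = "generic") -> pd.DataFrame:
    """Read a features x samples TSV.

    Empty cells / NA / NaN parse to missing values, which are rejected for
    every layer except the metabolome. Duplicate feature or sample ids and
    non-numeric cells raise with the offending id or location.
    """
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}")
    # the csv reader mangles duplicate header names, so check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    col_idx = pd.Index(header)
    if col_idx.duplicated().any():
        dups = col_idx[col_idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s) in {path}: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["", "NA", "NaN"],
                     keep_default_na=False)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature id(s) in {path}: {dups}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric cell at feature {row!r}, sample {col!r} in {path}")
        raise
    if layer != "metabolome" and df.isna().any().any():
        loc = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at feature {df.index[loc[0]]!r}, sample "
            f"{df.columns[loc[1]]!r}: empty cells are only allowed in the metabolome layer")
    return df


def write_matrix(df: pd.DataFrame, path, float_format: str = "%.12g") -> None:
    """Write a features x samples matrix as TSV (missing values as empty cells)."""
    df.to_csv(path, sep="\t", float_format=float_format, na_rep="")


def read_design(path) -> pd.DataFrame:
    return validate_design(pd.read_csv(path, sep="\t"))


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"genus", "phylum"}.issubset(df.columns):
        raise ValueError("taxonomy table needs columns genus, phylum")
    return df


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_pathway_map(path) -> dict:
    """Two-column TSV (pathway_id, feature_id) -> {pathway: set of members}."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:2])
    out: dict[str, set] = {}
    for pw, feat in zip(df[cols[0]].astype(str), df[cols[1]].astype(str)):
        out.setdefault(pw, set()).add(feat)
    return out


def pathway_map_from_annotation(annotations: pd.DataFrame) -> dict:
    """Pathway map from the annotation sidecar's semicolon-separated column."""
    out: dict[str, set] = {}
    for mid, pws in zip(annotations["metabolite_id"].astype(str),
                        annotations["pathways"].fillna("")):
        for pw in str(pws).split(";"):
            if pw:
                out.setdefault(pw, set()).add(mid)
    return out


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_study(study, outdir) -> dict:
    """Write all tables of a SimulatedStudy; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "design": outdir / "design.tsv",
        "genus_counts": outdir / "genus_counts.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "metabolite_intensities": outdir / "metabolite_intensities.tsv",
        "annotations": outdir / "metabolite_annotations.tsv",
        "gene_counts": outdir / "gene_counts.tsv",
        "truth_labels": outdir / "ground_truth_labels.tsv",
        "truth_cascades": outdir / "ground_truth_cascades.tsv",
    }
    write_design(study.design, paths["design"])
    write_matrix(study.genus_counts, paths["genus_counts"])
    study.taxonomy.to_csv(paths["taxonomy"], sep="\t", index=False)
    write_matrix(study.metabolite_intensities, paths["metabolite_intensities"])
    study.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    write_matrix(study.gene_counts, paths["gene_counts"])
    study.truth_labels.to_csv(paths["truth_labels"], sep="\t", index=False)
    study.truth_cascades.to_csv(paths["truth_cascades"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
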