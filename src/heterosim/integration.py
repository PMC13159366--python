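"""Cross-omics association analysis.

CLR-transformed genus abundances are correlated with processed metabolite
intensities (Spearman, |rho| > 0.4, BH-FDR q < 0.05 within the cross-layer
family); metabolite-metabolite co-regulation edges use |rho| > 0.6; gene
expression is normalized by median-of-ratios size factors + log2 and
nonadditive genes are linked to metabolites; genus-metabolite-gene cascade
triads join the two edge families on the shared metabolite. Pathway
enrichment is a one-sided hypergeometric test over a user-supplied pathway
map.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .community import Network, _correlation_edges


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1,
    order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlate_layers(A: pd.DataFrame, B: pd.DataFrame, r_min: float = 0.4,
                     q_max: float | None = 0.05) -> pd.DataFrame:
    """Spearman edges between two layers over their shared samples.

    A must already be on its analysis scale (CLR for the microbiome). BH is
    applied across the full cross-pair family; edges retained at
    |rho| > r_min and q < q_max (strict).
    """
    shared = [s for s in A.columns if s in set(B.columns)]
    if len(shared) < 5:
        raise ValueError("need at least 5 shared samples")
    return _correlation_edges(A[shared], B[shared], r_min, q_max)


def metabolite_metabolite_edges(X: pd.DataFrame, r_min: float = 0.6,
                                q_max: float | None = None) -> pd.DataFrame:
    """Within-metabolome co-regulation edges at |rho| > r_min (no FDR gate
    by default; q is still reported)."""
    if X.shape[1] < 5:
        raise ValueError("need at least 5 samples")
    return _correlation_edges(X, None, r_min, q_max)


def normalize_expression(counts: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilizing-style normalization of gene counts.

    Median-of-ratios size factors (geometric-mean reference over genes with
    all-positive counts) followed by log2(count / size_factor + 1). Falls
    back to library-size factors when no gene is positive in every sample.
    """
    C = counts.to_numpy(dtype=float)
    if (C < 0).any():
        raise ValueError("counts must be non-negative")
    allpos = (C > 0).all(axis=1)
    if allpos.any():
        logref = np.log(C[allpos]).mean(axis=1)
        sf = np.exp(np.median(np.log(C[allpos]) - logref[:, None], axis=0))
    else:
        warnings.warn("no gene detected in every sample; using library-size factors")
        lib = C.sum(axis=0)
        sf = lib / np.exp(np.mean(np.log(lib)))
    out = np.log2(C / sf[None, :] + 1.0)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def link_metabolites_to_genes(metabolites: pd.DataFrame, expression: pd.DataFrame,
                              nonadditive_genes, r_min: float = 0.4,
                              q_max: float | None = 0.05) -> pd.DataFrame:
    """Spearman metabolite-gene edges restricted to nonadditive genes.

    BH within this family; unknown gene ids raise with the offending ids.
    """
    gene_ids = [str(g) for g in nonadditive_genes]
    unknown = sorted(set(gene_ids) - set(expression.index.astype(str)))
    if unknown:
        raise ValueError(f"unknown gene id(s): {unknown[:10]}")
    if not gene_ids:
        return pd.DataFrame(columns=["source", "target", "rho", "p", "q", "sign"])
    sub = expression.loc[expression.index.astype(str).isin(set(gene_ids))]
    return correlate_layers(metabolites, sub, r_min=r_min, q_max=q_max)


@dataclass
class CascadeTriad:
    genus_id: str
    metabolite_id: str
    gene_id: str
    rho_genus_metabolite: float
    rho_metabolite_gene: float


def build_cascades(genus_metabolite_edges: pd.DataFrame,
                   metabolite_gene_edges: pd.DataFrame) -> pd.DataFrame:
    """Genus-metabolite-gene triads: join the two edge families on the
    shared metabolite. Deduplicated; the triad count equals
    sum_m genus_degree(m) * gene_degree(m)."""
    cols = ["genus_id", "metabolite_id", "gene_id", "rho_genus_metabolite",
            "rho_metabolite_gene"]
    if genus_metabolite_edges.empty or metabolite_gene_edges.empty:
        return pd.DataFrame(columns=cols)
    gm = genus_metabolite_edges.rename(
        columns={"source": "genus_id", "target": "metabolite_id",
                 "rho": "rho_genus_metabolite"})
    mg = metabolite_gene_edges.rename(
        columns={"source": "metabolite_id", "target": "gene_id",
                 "rho": "rho_metabolite_gene"})
    triads = gm[["genus_id", "metabolite_id", "rho_genus_metabolite"]].merge(
        mg[["metabolite_id", "gene_id", "rho_metabolite_gene"]], on="metabolite_id")
    return triads.drop_duplicates(subset=["genus_id", "metabolite_id", "gene_id"]
                                  ).reset_index(drop=True)[cols]


def cascade_summary(triads: pd.DataFrame) -> dict:
    """Per-genus and per-metabolite triad counts."""
    if triads.empty:
        return {"n_triads": 0, "per_genus": {}, "per_metabolite": {}}
    return {
        "n_triads": len(triads),
        "per_genus": triads.groupby("genus_id").size().to_dict(),
        "per_metabolite": triads.groupby("metabolite_id").size().to_dict(),
    }


def hypergeometric_enrichment(query_ids, pathway_map: dict, universe=None,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Over-representation of query features in pathways.

    pathway_map: pathway_id -> iterable of member feature ids. The universe
    defaults to the union of all pathway members. Query ids outside the
    universe are dropped with a warning. For each pathway with K members,
    a query of size n and k hits in a universe of N,
    p = P(X >= k) under Hypergeometric(N, K, n); sorted by p, flagged
    significant at p < alpha.
    """
    if universe is None:
        universe = set().union(*[set(v) for v in pathway_map.values()]) if pathway_map else set()
    universe = {str(u) for u in universe}
    query = {str(q) for q in query_ids}
    outside = query - universe
    if outside:
        warnings.warn(f"dropping {len(outside)} query id(s) outside the universe")
        query &= universe
    if not query:
        raise ValueError("empty query after intersecting with the universe")
    N, n = len(universe), len(query)
    rows = []
    for pid, members in pathway_map.items():
        members = {str(m) for m in members} & universe
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway_id": pid, "k": k, "n": n, "K": K, "N": N,
                     "p_value": p, "significant": p < alpha})
    return pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)


def tripartite_network(genus_metabolite_edges: pd.DataFrame,
                       metabolite_gene_edges: pd.DataFrame) -> Network:
    """Merge the two cross-layer edge families into one node/edge table pair
    for export (GraphML / edge-list TSV)."""
    edges = pd.concat([genus_metabolite_edges, metabolite_gene_edges],
                      ignore_index=True)
    layer = {}
    for _, r in genus_metabolite_edges.iterrows():
        layer[r["source"]] = "microbiome"
        layer[r["target"]] = "metabolome"
    for _, r in metabolite_gene_edges.iterrows():
        layer[r["source"]] = "metabolome"
        layer[r["target"]] = "transcriptome"
    nodes = pd.DataFrame({"id": list(layer), "layer": list(layer.values()),
                          "label": "", "abundance": np.nan})
    return Network(nodes=nodes, edges=edges, r_min=np.nan, q_max=None)
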