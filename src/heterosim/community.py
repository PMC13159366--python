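"""Genus-table community analysis: prevalence filtering, relative
abundance, CLR, alpha/beta diversity, NMDS ordination, phylum summaries and
within-layer co-occurrence networks.

All module-level functions take features x samples DataFrames (the layer
orientation used by the file formats); the sklearn-style estimators
(`CLRTransformer`, `PrevalenceFilter`) follow the sklearn samples x features
convention and are what the functions delegate to.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from . import _stats
from ._nmds import NMDS, kruskal_stress
from .design import GROUP_ALIASES, GROUPS, split_by_group
from .heterosis import pairwise_tables

__all__ = [
    "PrevalenceFilter", "CLRTransformer", "NMDS", "Network",
    "prevalence_filter", "relative_abundance", "clr_transform",
    "gini_simpson", "observed_richness", "bray_curtis", "nmds",
    "phylum_summary", "diversity_tests", "cooccurrence_network",
    "cooccurrence_networks_by_group", "network_topology", "kruskal_stress",
]


# ---------------------------------------------------------------------------
# Estimators (samples x features orientation)
# ---------------------------------------------------------------------------

class PrevalenceFilter(TransformerMixin, BaseEstimator):
    """Keep features detected (value > 0) in strictly more than
    ``min_prevalence`` of the samples seen at fit time."""

    def __init__(self, min_prevalence: float = 0.6):
        self.min_prevalence = min_prevalence

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if (X < 0).any():
            raise ValueError("counts must be non-negative")
        prev = (X > 0).mean(axis=0)
        self.prevalence_ = prev
        self.support_ = prev > self.min_prevalence
        if not self.support_.any():
            warnings.warn("prevalence filter removed every feature")
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]


class CLRTransformer(TransformerMixin, BaseEstimator):
    """Centered log-ratio transform of compositions (rows sum to 1).

    Zeros are handled by multiplicative replacement: within each sample,
    zero parts are set to delta = delta_factor x (smallest nonzero
    proportion in that sample) and the nonzero parts are rescaled by
    (1 - n_zero * delta) so the composition stays closed. The CLR of each
    sample sums to zero and is invariant to a positive rescaling of the
    sample's raw counts.
    """

    def __init__(self, zero_handling: str = "multiplicative", delta_factor: float = 0.65):
        self.zero_handling = zero_handling
        self.delta_factor = delta_factor

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        P = np.asarray(X, dtype=float)
        if (P < 0).any():
            raise ValueError("proportions must be non-negative")
        if np.any(P.sum(axis=1) == 0):
            raise ValueError("all-zero sample cannot be CLR-transformed")
        P = P / P.sum(axis=1, keepdims=True)
        if (P == 0).any():
            if self.zero_handling == "multiplicative":
                P = self._replace_zeros(P)
            elif self.zero_handling == "error":
                raise ValueError("zeros present and zero_handling='error'")
            else:
                raise ValueError(f"unknown zero_handling {self.zero_handling!r}")
        L = np.log(P)
        return L - L.mean(axis=1, keepdims=True)

    def _replace_zeros(self, P):
        out = P.copy()
        for i in range(P.shape[0]):
            row = P[i]
            zero = row == 0
            if not zero.any():
                continue
            delta = self.delta_factor * row[~zero].min()
            out[i, zero] = delta
            out[i, ~zero] = row[~zero] * (1.0 - zero.sum() * delta)
        return out


# ---------------------------------------------------------------------------
# Functional surface (features x samples DataFrames)
# ---------------------------------------------------------------------------

def prevalence_filter(counts: pd.DataFrame, min_prevalence: float = 0.6,
                      design: pd.DataFrame | None = None,
                      per_group: bool = False) -> pd.DataFrame:
    """Retain genera present in strictly more than ``min_prevalence`` of samples.

    Prevalence is computed over the pooled cohort by default; with
    ``per_group=True`` (requires ``design``) a genus is kept if it clears the
    threshold within every group.
    """
    if per_group:
        if design is None:
            raise ValueError("per_group prevalence needs a design table")
        keep = np.ones(counts.shape[0], dtype=bool)
        for block in split_by_group(counts, design).values():
            keep &= (block.to_numpy(dtype=float) > 0).mean(axis=1) > min_prevalence
        if not keep.any():
            warnings.warn("prevalence filter removed every feature")
        return counts.loc[keep]
    f = PrevalenceFilter(min_prevalence).fit(counts.T.to_numpy(dtype=float))
    return counts.loc[f.support_]


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample closure: each column divided by its total (columns sum to 1)."""
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return counts / totals


def clr_transform(proportions: pd.DataFrame, zero_handling: str = "multiplicative",
                  delta_factor: float = 0.65) -> pd.DataFrame:
    """CLR transform of a features x samples proportion table."""
    t = CLRTransformer(zero_handling=zero_handling, delta_factor=delta_factor)
    out = t.fit_transform(proportions.T.to_numpy(dtype=float)).T
    return pd.DataFrame(out, index=proportions.index, columns=proportions.columns)


def gini_simpson(proportions: pd.DataFrame, form: str = "gini_simpson") -> pd.Series:
    """Simpson diversity per sample: 1 - sum p_i^2 (or sum p_i^2 with
    form='simpson')."""
    P = proportions.to_numpy(dtype=float)
    sums = P.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-8):
        raise ValueError("per-sample proportions must sum to 1")
    lam = (P ** 2).sum(axis=0)
    vals = lam if form == "simpson" else 1.0 - lam
    return pd.Series(vals, index=proportions.columns, name=form)


def observed_richness(counts: pd.DataFrame) -> pd.Series:
    """Number of features with count > 0, per sample."""
    return (counts > 0).sum(axis=0).rename("richness")


def bray_curtis(X: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples (columns) of X."""
    M = X.T.to_numpy(dtype=float)
    if (M < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    if (M.sum(axis=1) == 0).sum() >= 2:
        raise ValueError("two all-zero samples: Bray-Curtis undefined for that pair")
    D = squareform(pdist(M, metric="braycurtis"))
    return pd.DataFrame(D, index=X.columns, columns=X.columns)


def nmds(D: pd.DataFrame, k: int = 2, n_restarts: int = 4, seed: int | None = 0) -> NMDS:
    """Fit the in-package NMDS on a distance DataFrame; returns the estimator."""
    model = NMDS(n_components=k, n_restarts=n_restarts, random_state=seed)
    model.fit(D.to_numpy(dtype=float))
    return model


def diversity_tests(values: pd.Series, design: pd.DataFrame, test: str = "wilcoxon"
                    ) -> pd.DataFrame:
    """Pairwise group tests of a per-sample diversity index."""
    X = values.to_frame().T
    X.index = [values.name or "diversity"]
    tables = pairwise_tables(X, design, test=test)
    return pd.DataFrame({name: {"statistic": t["statistic"].iloc[0],
                                "p_value": t["p_value"].iloc[0],
                                "direction": int(t["direction"].iloc[0])}
                         for name, t in tables.items()}).T


def phylum_summary(counts: pd.DataFrame, taxonomy: pd.DataFrame,
                   design: pd.DataFrame) -> pd.DataFrame:
    """Mean per-sample phylum composition per group (rows sum to 1).

    ``taxonomy`` maps genus -> phylum (columns genus, phylum); genera
    missing from it are labelled 'unassigned'.
    """
    tax = dict(zip(taxonomy["genus"].astype(str), taxonomy["phylum"].astype(str)))
    phyla = pd.Series([tax.get(str(g), "unassigned") for g in counts.index],
                      index=counts.index)
    rel = relative_abundance(counts)
    by_phylum = rel.groupby(phyla).sum()  # phyla x samples
    rows = {}
    for g, block in split_by_group(by_phylum, design).items():
        rows[GROUP_ALIASES[g]] = block.mean(axis=1)
    out = pd.DataFrame(rows).T
    return out.div(out.sum(axis=1), axis=0)


# ---------------------------------------------------------------------------
# Co-occurrence networks
# ---------------------------------------------------------------------------

@dataclass
class Network:
    """Thresholded correlation network: node table + edge table."""
    nodes: pd.DataFrame  # id, layer, label (phylum / chemical class), abundance
    edges: pd.DataFrame  # source, target, rho, p, q, sign
    r_min: float = 0.4
    q_max: float | None = 0.05

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        for _, row in self.nodes.iterrows():
            G.add_node(row["id"], **{k: row[k] for k in self.nodes.columns if k != "id"})
        for _, row in self.edges.iterrows():
            G.add_edge(row["source"], row["target"], rho=float(row["rho"]),
                       p=float(row["p"]), q=float(row["q"]), sign=int(row["sign"]))
        return G

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _correlation_edges(A: pd.DataFrame, B: pd.DataFrame | None, r_min: float,
                       q_max: float | None) -> pd.DataFrame:
    """All-pairs Spearman edges between rows of A (and B), BH-adjusted
    within this family, retained at |rho| > r_min and (if set) q < q_max."""
    within = B is None
    rho, p = _stats.spearman_rows(A.to_numpy(dtype=float),
                                  None if within else B.to_numpy(dtype=float))
    a_ids = list(A.index)
    b_ids = a_ids if within else list(B.index)
    if within:
        ii, jj = np.triu_indices(len(a_ids), k=1)
    else:
        ii, jj = np.indices((len(a_ids), len(b_ids)))
        ii, jj = ii.ravel(), jj.ravel()
    rho_f = rho[ii, jj]
    p_f = p[ii, jj]
    ok = ~np.isnan(rho_f)
    if (~ok).any():
        warnings.warn(f"skipped {int((~ok).sum())} pairs involving constant features")
    q_f = np.full_like(p_f, np.nan)
    if ok.any():
        q_f[ok] = multipletests(p_f[ok], method="fdr_bh")[1]
    keep = ok & (np.abs(rho_f) > r_min)
    if q_max is not None:
        keep &= q_f < q_max
    return pd.DataFrame({
        "source": [a_ids[i] for i in ii[keep]],
        "target": [b_ids[j] for j in jj[keep]],
        "rho": rho_f[keep],
        "p": p_f[keep],
        "q": q_f[keep],
        "sign": np.sign(rho_f[keep]).astype(int),
    })


def cooccurrence_network(clr: pd.DataFrame, r_min: float = 0.4, q_max: float = 0.05,
                         taxonomy: pd.DataFrame | None = None) -> Network:
    """Genus co-occurrence network from a CLR matrix (features x samples).

    Spearman over all genus pairs, BH across all pairs of this network,
    edges at |rho| > r_min and q < q_max (strict inequalities).
    """
    if clr.shape[1] < 5:
        raise ValueError("need at least 5 samples for correlation networks")
    edges = _correlation_edges(clr, None, r_min, q_max)
    tax = {}
    if taxonomy is not None:
        tax = dict(zip(taxonomy["genus"].astype(str), taxonomy["phylum"].astype(str)))
    nodes = pd.DataFrame({
        "id": clr.index.astype(str),
        "layer": "microbiome",
        "label": [tax.get(str(g), "unassigned") for g in clr.index],
        "abundance": clr.mean(axis=1).to_numpy(),
    })
    return Network(nodes=nodes, edges=edges, r_min=r_min, q_max=q_max)


def cooccurrence_networks_by_group(clr: pd.DataFrame, design: pd.DataFrame,
                                   r_min: float = 0.4, q_max: float = 0.05,
                                   taxonomy: pd.DataFrame | None = None
                                   ) -> dict[str, Network]:
    """One network per group (CC, CR, RR), built on the group's samples only."""
    return {GROUP_ALIASES[g]: cooccurrence_network(block, r_min, q_max, taxonomy)
            for g, block in split_by_group(clr, design).items()}


def network_topology(network: Network | nx.Graph) -> dict:
    """Node/edge counts, density, mean degree, mean clustering, greedy-
    modularity community modularity, and the per-node degree table."""
    G = network.to_networkx() if isinstance(network, Network) else network
    n, m = G.number_of_nodes(), G.number_of_edges()
    if m == 0:
        warnings.warn("empty network: topology metrics are zero")
        return {"n_nodes": n, "n_edges": 0, "density": 0.0, "mean_degree": 0.0,
                "mean_clustering": 0.0, "modularity": 0.0,
                "degree_table": pd.DataFrame(columns=["node", "degree"])}
    comms = nx.algorithms.community.greedy_modularity_communities(G)
    degree = pd.DataFrame(sorted(G.degree, key=lambda kv: -kv[1]),
                          columns=["node", "degree"])
    return {
        "n_nodes": n,
        "n_edges": m,
        "density": nx.density(G),
        "mean_degree": 2.0 * m / n,
        "mean_clustering": nx.average_clustering(G),
        "modularity": nx.algorithms.community.modularity(G, comms),
        "degree_table": degree,
    }
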