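"""End-to-end pipeline: simulate (or load) -> microbiome community analysis
-> genus heterosis -> metabolome preprocessing + differential calling ->
metabolite heterosis/patterns -> transcriptome normalization + patterns ->
cross-omics networks and cascades -> enrichment.

The run report records every threshold actually used and the feature counts
surviving each filter, so the many cut-offs are auditable; the run is
deterministic given the seed.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, integration, io, metabolome
from .heterosis import heterosis_analysis, summarize_patterns
from .simulate import SimConfig, simulate_study


@dataclass
class PipelineConfig:
    """Thresholds, test choices and paths for one pipeline run."""
    out_dir: str = "heterosim_out"
    seed: int = 0
    alpha: float = 0.05
    prevalence: float = 0.6
    max_missing: float = 0.5
    vip_threshold: float = 1.0
    r_min_network: float = 0.4
    q_max_network: float = 0.05
    r_min_metmet: float = 0.6
    r_min_cross: float = 0.4
    q_max_cross: float = 0.05
    pairwise_test: str = "wilcoxon"
    heterosis_method: str = "welch"
    nmds_restarts: int = 4
    genus_subset: list | None = None
    # input paths; if absent the synthetic generator provides the data
    design: str | None = None
    genus_counts: str | None = None
    taxonomy: str | None = None
    metabolite_intensities: str | None = None
    annotations: str | None = None
    gene_counts: str | None = None
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> "PipelineConfig":
        for name, v, lo, hi in [("alpha", self.alpha, 0, 1),
                                ("prevalence", self.prevalence, 0, 1),
                                ("max_missing", self.max_missing, 0, 1),
                                ("q_max_network", self.q_max_network, 0, 1),
                                ("q_max_cross", self.q_max_cross, 0, 1)]:
            if not (lo < v < hi if name == "alpha" else lo <= v <= hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi})")
        for name, v in [("r_min_network", self.r_min_network),
                        ("r_min_metmet", self.r_min_metmet),
                        ("r_min_cross", self.r_min_cross)]:
            if not 0 <= v < 1:
                raise ValueError(f"{name}={v} outside [0, 1)")
        return self


def _load_inputs(cfg: PipelineConfig):
    if cfg.genus_counts:
        design = io.read_design(cfg.design)
        counts = io.read_matrix(cfg.genus_counts, "microbiome")
        taxonomy = io.read_taxonomy(cfg.taxonomy) if cfg.taxonomy else None
        intens = io.read_matrix(cfg.metabolite_intensities, "metabolome") \
            if cfg.metabolite_intensities else None
        ann = io.read_annotation(cfg.annotations) if cfg.annotations else None
        genes = io.read_matrix(cfg.gene_counts, "transcriptome") \
            if cfg.gene_counts else None
        return design, counts, taxonomy, intens, ann, genes
    study = simulate_study(SimConfig(**cfg.sim), seed=cfg.seed)
    return (study.design, study.genus_counts, study.taxonomy,
            study.metabolite_intensities, study.annotations, study.gene_counts)


def run_pipeline(cfg: PipelineConfig, write: bool = True) -> dict:
    """Execute all stages in order and return the machine-readable report."""
    cfg.validate()
    out = Path(cfg.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"thresholds": {
        "alpha": cfg.alpha, "prevalence": cfg.prevalence,
        "max_missing": cfg.max_missing, "vip_threshold": cfg.vip_threshold,
        "r_min_network": cfg.r_min_network, "q_max_network": cfg.q_max_network,
        "r_min_metmet": cfg.r_min_metmet, "r_min_cross": cfg.r_min_cross,
        "q_max_cross": cfg.q_max_cross, "pairwise_test": cfg.pairwise_test,
        "heterosis_method": cfg.heterosis_method, "seed": cfg.seed,
    }}
    try:
        design, counts, taxonomy, intens, ann, genes = _load_inputs(cfg)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise RuntimeError(f"stage 'load_inputs' failed: {exc}") from exc

    # ---- microbiome community + heterosis --------------------------------
    try:
        filtered = community.prevalence_filter(counts, cfg.prevalence)
        rel = community.relative_abundance(filtered)
        clr = community.clr_transform(rel)
        simpson = community.gini_simpson(community.relative_abundance(counts))
        richness = community.observed_richness(counts)
        bc = community.bray_curtis(rel)
        ord_model = community.nmds(bc, k=2, n_restarts=cfg.nmds_restarts, seed=cfg.seed)
        phyla = (community.phylum_summary(filtered, taxonomy, design)
                 if taxonomy is not None else None)
        networks = community.cooccurrence_networks_by_group(
            clr, design, cfg.r_min_network, cfg.q_max_network, taxonomy)
        genus_het = heterosis_analysis(rel, design, alpha=cfg.alpha,
                                       test=cfg.pairwise_test,
                                       method=cfg.heterosis_method, seed=cfg.seed)
        het_sig = genus_het["p_value"] < cfg.alpha
        f1_cols = design.loc[design["group"] == "F1", "sample_id"]
        cum_abund = float(rel.loc[het_sig[het_sig].index, f1_cols].mean(axis=1).sum())
        report["microbiome"] = {
            "n_genera_input": int(counts.shape[0]),
            "n_genera_after_prevalence": int(filtered.shape[0]),
            "n_heterotic_genera": int(het_sig.sum()),
            "n_positive_heterosis": int((genus_het["direction"] == "positive").sum()),
            "n_negative_heterosis": int((genus_het["direction"] == "negative").sum()),
            "heterotic_cumulative_abundance_pct": 100.0 * cum_abund,
            "nmds_stress": float(ord_model.stress_),
            "network_edges": {g: net.n_edges for g, net in networks.items()},
            "simpson_tests": community.diversity_tests(
                simpson, design, cfg.pairwise_test)["p_value"].to_dict(),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'microbiome' failed: {exc}") from exc

    # ---- metabolome ------------------------------------------------------
    met_processed = met_log10 = met_calls = None
    if intens is not None:
        try:
            met_processed, audit = metabolome.preprocess(
                intens, design, annotations=ann, max_missing=cfg.max_missing)
            kept = met_processed.index
            met_log10 = np.log10(metabolome.impute_half_min(
                metabolome.filter_missingness(
                    intens.loc[intens.index.isin(set(kept))], design,
                    cfg.max_missing)))
            pls = metabolome.plsda_fit(met_processed, design, n_components=2, cv=5)
            met_calls = metabolome.differential_metabolites(
                met_processed, design, vip_threshold=cfg.vip_threshold,
                alpha=cfg.alpha, test=cfg.pairwise_test)
            diff_counts = metabolome.differential_summary(met_calls)
            # metabolite heterosis is computed on log10 relative content
            met_het = heterosis_analysis(met_log10, design, alpha=cfg.alpha,
                                         test=cfg.pairwise_test,
                                         method=cfg.heterosis_method, seed=cfg.seed)
            diff_ids = set(met_calls.loc[met_calls["called"], "metabolite_id"])
            pat = met_het.loc[met_het.index.astype(str).isin(diff_ids)]
            summary = (summarize_patterns(pat[["category", "subcategory"]])
                       if len(pat) else None)
            nonadd = met_het.index[met_het["nonadditive"]].astype(str)
            partition = (metabolome.source_partition(nonadd, ann)
                         if ann is not None else None)
            report["metabolome"] = {
                "preprocess_audit": audit,
                "plsda_explained_y_variance": [float(v) for v in pls.explained_y_variance_],
                "plsda_q2": float(getattr(pls, "q2_", np.nan)),
                "differential_counts": {c: row.to_dict()
                                        for c, row in diff_counts.iterrows()},
                "pattern_summary": summary,
                "n_nonadditive": int(len(nonadd)),
                "origin_counts": partition["counts"] if partition else None,
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'metabolome' failed: {exc}") from exc

    # ---- transcriptome + integration -------------------------------------
    if genes is not None and met_processed is not None:
        try:
            expr = integration.normalize_expression(genes)
            gene_het = heterosis_analysis(expr, design, alpha=cfg.alpha,
                                          test=cfg.pairwise_test,
                                          method=cfg.heterosis_method, seed=cfg.seed)
            nonadd_genes = gene_het.index[gene_het["nonadditive"]].astype(str)
            genera = clr
            if cfg.genus_subset:
                genera = clr.loc[clr.index.astype(str).isin(set(map(str, cfg.genus_subset)))]
            else:
                het_genera = genus_het.index[(genus_het["p_value"] < cfg.alpha)]
                genera = clr.loc[clr.index.isin(het_genera)]
            gm_edges = integration.correlate_layers(
                genera, met_processed, cfg.r_min_cross, cfg.q_max_cross) \
                if len(genera) else pd.DataFrame(
                    columns=["source", "target", "rho", "p", "q", "sign"])
            mm_edges = integration.metabolite_metabolite_edges(
                met_processed, cfg.r_min_metmet)
            mg_edges = integration.link_metabolites_to_genes(
                met_processed, expr, nonadd_genes, cfg.r_min_cross, cfg.q_max_cross) \
                if len(nonadd_genes) else pd.DataFrame(
                    columns=["source", "target", "rho", "p", "q", "sign"])
            triads = integration.build_cascades(gm_edges, mg_edges)
            enrich = None
            if ann is not None:
                pw_map = io.pathway_map_from_annotation(ann)
                linked_mets = sorted(set(gm_edges["target"]))
                in_universe = set().union(*pw_map.values()) if pw_map else set()
                if pw_map and set(linked_mets) & in_universe:
                    enrich = integration.hypergeometric_enrichment(
                        [m for m in linked_mets if m in in_universe], pw_map,
                        alpha=cfg.alpha)
            report["integration"] = {
                "n_focal_genera": int(len(genera)),
                "n_nonadditive_genes": int(len(nonadd_genes)),
                "n_genus_metabolite_edges": int(len(gm_edges)),
                "n_metabolite_metabolite_edges": int(len(mm_edges)),
                "n_metabolite_gene_edges": int(len(mg_edges)),
                "n_cascade_triads": int(len(triads)),
                "n_linked_metabolites": int(gm_edges["target"].nunique()) if len(gm_edges) else 0,
                "n_linked_genes": int(mg_edges["target"].nunique()) if len(mg_edges) else 0,
                "n_enriched_pathways": int(enrich["significant"].sum()) if enrich is not None else 0,
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'integration' failed: {exc}") from exc

    if write:
        try:
            _write_outputs(out, locals())
        except Exception as exc:
            raise RuntimeError(f"stage 'write_outputs' failed: {exc}") from exc
    return report


def _write_outputs(out: Path, ns: dict) -> None:
    io.write_matrix(ns["rel"], out / "genus_relative_abundance.tsv")
    io.write_matrix(ns["clr"], out / "genus_clr.tsv")
    pd.DataFrame({"simpson": ns["simpson"], "richness": ns["richness"]}).to_csv(
        out / "alpha_diversity.tsv", sep="\t")
    io.write_matrix(ns["bc"], out / "bray_curtis.tsv")
    ordn = pd.DataFrame(ns["ord_model"].embedding_,
                        index=ns["bc"].index, columns=["NMDS1", "NMDS2"])
    ordn["stress"] = ns["ord_model"].stress_
    ordn.to_csv(out / "nmds.tsv", sep="\t")
    if ns["phyla"] is not None:
        ns["phyla"].to_csv(out / "phylum_summary.tsv", sep="\t")
    for gname, net in ns["networks"].items():
        io.write_edges(net.edges, out / f"network_{gname}_edges.tsv")
        net.write_graphml(out / f"network_{gname}.graphml")
    ns["genus_het"].to_csv(out / "genus_heterosis.tsv", sep="\t")
    if ns.get("met_calls") is not None:
        ns["met_calls"].to_csv(out / "metabolite_differential.tsv", sep="\t", index=False)
        ns["met_het"].to_csv(out / "metabolite_heterosis.tsv", sep="\t")
    if "gm_edges" in ns:
        io.write_edges(ns["gm_edges"], out / "genus_metabolite_edges.tsv")
        io.write_edges(ns["mm_edges"], out / "metabolite_metabolite_edges.tsv")
        io.write_edges(ns["mg_edges"], out / "metabolite_gene_edges.tsv")
        ns["triads"].to_csv(out / "cascade_triads.tsv", sep="\t", index=False)
        integration.tripartite_network(ns["gm_edges"], ns["mg_edges"]).write_graphml(
            out / "tripartite_network.graphml")
        if ns.get("enrich") is not None:
            ns["enrich"].to_csv(out / "pathway_enrichment.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(ns["report"], fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
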