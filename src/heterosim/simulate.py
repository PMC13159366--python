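"""Synthetic three-group multi-omics generator with known ground truth.

Emulates the study design this package targets: two parental broiler lines
and their crossbred progeny (default group sizes 91/90/85), a compositional
genus count table, a log-normal LC-MS metabolite intensity matrix with
missing-not-at-random dropout, and a negative-binomial gene count matrix.
Heterosis patterns are planted as group-wise mean shifts on the log scale,
and genus -> metabolite -> gene cascades share a standard-normal latent
factor per triad.

Planted group offsets, in units of the layer's within-group SD
(effect_size = e), for (P1, F1, P2):

    null                ( 0,  0,  0)
    additive            (+e,  0, -e)   hybrid at the mid-parent
    dominance_high      (+e, +e, -e)   hybrid matches the high parent
    dominance_low       (+e, -e, -e)   hybrid matches the low parent
    overdominance_high  ( 0, +e,  0)   hybrid above both parents
    overdominance_low   ( 0, -e,  0)   hybrid below both parents

A cascade feature with loading lambda is lambda*Z + sqrt(1-lambda^2)*eps on
the standardized log scale (unit total variance), so two features of one
triad have cross-layer correlation lambda^2 (0.81 at the default 0.9).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import GROUP_ALIASES, GROUPS, validate_design

PATTERNS = ("additive", "dominance_high", "dominance_low",
            "overdominance_high", "overdominance_low", "null")

#: offsets in SD units for (P1, F1, P2)
_OFFSETS = {
    "null": (0.0, 0.0, 0.0),
    "additive": (1.0, 0.0, -1.0),
    "dominance_high": (1.0, 1.0, -1.0),
    "dominance_low": (1.0, -1.0, -1.0),
    "overdominance_high": (0.0, 1.0, 0.0),
    "overdominance_low": (0.0, -1.0, 0.0),
}

_PHYLA = ("Firmicutes", "Bacteroidota", "Proteobacteria", "Actinobacteriota", "other")
_PHYLUM_P = (0.55, 0.20, 0.12, 0.08, 0.05)

_CLASSES = ("Lipids and lipid-like molecules", "Organic acids and derivatives",
            "Organoheterocyclic compounds", "Benzenoids",
            "Organic oxygen compounds", "Nucleosides, nucleotides, and analogues",
            "Other")
_CLASS_P = (0.46, 0.20, 0.10, 0.08, 0.06, 0.05, 0.05)

_ORIGINS = ("host", "microbiota", "co_metabolism", "other")
_ORIGIN_P = (0.25, 0.30, 0.25, 0.20)


@dataclass
class SimConfig:
    """Generator configuration; defaults are the study conditions."""
    n_per_group: tuple[int, int, int] = (91, 90, 85)
    n_genera: int = 150
    n_metabolites: int = 300
    n_genes: int = 400
    effect_size: float = 2.0
    pattern_mix: dict = field(default_factory=lambda: {
        "additive": 0.10, "dominance_high": 0.12, "dominance_low": 0.12,
        "overdominance_high": 0.04, "overdominance_low": 0.02, "null": 0.60})
    dropout: float | dict = 0.2
    nb_dispersion: float = 0.1
    depth: int = 50_000
    low_prevalence_fraction: float = 0.10
    n_force_missing: int = 0
    n_cascades: int = 5
    cascade_loading: float = 0.9
    cascade_spec: list | None = None  # list of (genus_idx, met_idx, gene_idx, loading)
    microbe_sigma: float = 1.0     # natural-log within-group SD of genus abundance
    metabolite_sigma: float = 0.5  # log10 within-group SD of metabolite intensity
    gene_sigma: float = 0.8        # natural-log biological SD of gene expression
    seed: int = 0

    def validate(self) -> "SimConfig":
        if any(n < 3 for n in self.n_per_group):
            raise ValueError("each group needs at least 3 samples (pairwise tests undefined)")
        if min(self.n_genera, self.n_metabolites, self.n_genes, self.depth) <= 0:
            raise ValueError("feature counts and depth must be positive")
        total = sum(self.pattern_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"pattern_mix must sum to 1, got {total}")
        if set(self.pattern_mix) - set(PATTERNS):
            raise ValueError(f"unknown pattern labels: {set(self.pattern_mix) - set(PATTERNS)}")
        drops = self.dropout.values() if isinstance(self.dropout, dict) else [self.dropout]
        if any(not (0 <= d < 1) for d in drops):
            raise ValueError("dropout must lie in [0, 1)")
        return self


@dataclass
class GroundTruth:
    """Planted structure: per-feature labels and cascade assignments."""
    labels: pd.DataFrame          # feature_id, layer, label
    cascades: pd.DataFrame        # cascade_id, genus_id, metabolite_id, gene_id, loading
    pattern_counts: dict          # layer -> {pattern: count}


def generate_design(n_per_group=(91, 90, 85), seed: int = 0) -> pd.DataFrame:
    """Sample table (sample_id, group) for the three-group design.

    Sample ids carry the display aliases (CC_###, CR_###, RR_###);
    deterministic for a given seed (the seed fixes nothing here beyond the
    contract that repeated calls are identical).
    """
    if any(n < 3 for n in n_per_group):
        raise ValueError("each group needs at least 3 samples (pairwise tests undefined)")
    rows = []
    for g, n in zip(GROUPS, n_per_group):
        alias = GROUP_ALIASES[g]
        rows += [{"sample_id": f"{alias}_{i + 1:03d}", "group": g} for i in range(n)]
    return validate_design(pd.DataFrame(rows), min_per_group=3)


# ---------------------------------------------------------------------------
# Shared deterministic plan
# ---------------------------------------------------------------------------

def _assign_labels(n_features: int, mix: dict, rng: np.random.Generator
                   ) -> tuple[np.ndarray, dict]:
    names = [p for p in PATTERNS if mix.get(p, 0) > 0]
    probs = np.array([mix[p] for p in names], dtype=float)
    counts = rng.multinomial(n_features, probs / probs.sum())
    labels = np.repeat(names, counts)
    rng.shuffle(labels)
    return labels, dict(zip(names, (int(c) for c in counts)))


def _plan(design: pd.DataFrame, config: SimConfig) -> dict:
    """Everything that must agree across the three layer generators:
    per-layer labels, cascade triads, and the shared latent factors."""
    config.validate()
    n_samples = len(design)
    plan = {}
    for layer, n_feat, code in (("microbiome", config.n_genera, 11),
                                ("metabolome", config.n_metabolites, 12),
                                ("transcriptome", config.n_genes, 13)):
        rng = np.random.default_rng([config.seed % (2 ** 31), code])
        labels, counts = _assign_labels(n_feat, config.pattern_mix, rng)
        plan[layer] = {"labels": labels, "counts": counts}
    spec = config.cascade_spec
    if spec is None:
        spec = []
        for c in range(config.n_cascades):
            idxs = []
            for layer, n_feat in (("microbiome", config.n_genera),
                                  ("metabolome", config.n_metabolites),
                                  ("transcriptome", config.n_genes)):
                null_idx = np.flatnonzero(plan[layer]["labels"] == "null")
                if len(null_idx) < config.n_cascades:
                    raise ValueError("not enough null features to host the cascades")
                idxs.append(int(null_idx[-(c + 1)]))
            spec.append((*idxs, config.cascade_loading))
    rng_z = np.random.default_rng([config.seed % (2 ** 31), 99])
    plan["latents"] = rng_z.normal(size=(len(spec), n_samples))
    plan["cascades"] = spec
    return plan


def _group_offsets(design: pd.DataFrame, labels: np.ndarray, effect: float
                   ) -> np.ndarray:
    """features x samples matrix of planted offsets in SD units."""
    gidx = {"P1": 0, "F1": 1, "P2": 2}
    cols = np.array([gidx[g] for g in design["group"]])
    per_label = np.array([_OFFSETS[l] for l in labels])  # n_feat x 3
    return effect * per_label[:, cols]


def _standardized_noise(plan, layer: str, feature_idx_to_cascade: dict,
                        shape: tuple, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise; cascade rows are lambda*Z + sqrt(1-lambda^2)*eps."""
    E = rng.normal(size=shape)
    for fi, (ci, lam) in feature_idx_to_cascade.items():
        E[fi] = lam * plan["latents"][ci] + np.sqrt(1.0 - lam ** 2) * E[fi]
    return E


def _cascade_map(plan, which: int) -> dict:
    return {spec[which]: (ci, spec[3]) for ci, spec in enumerate(plan["cascades"])}


# ---------------------------------------------------------------------------
# Layer generators
# ---------------------------------------------------------------------------

def generate_microbiome(design: pd.DataFrame, config: SimConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Genus count table (genera x samples), taxonomy sidecar, ground truth.

    Log-normal latent abundances with planted group structure are closed to
    compositions per sample and sampled multinomially at the configured
    depth. A fraction of null genera is made structurally rare (present in
    ~55% of samples) to exercise the 60% prevalence filter.
    """
    plan = _plan(design, config)
    labels = plan["microbiome"]["labels"]
    rng = np.random.default_rng([config.seed % (2 ** 31), 21])
    n_feat, n_samp = config.n_genera, len(design)
    base = rng.normal(0.0, 1.5, size=n_feat)
    noise = _standardized_noise(plan, "microbiome", _cascade_map(plan, 0),
                                (n_feat, n_samp), rng)
    log_abund = base[:, None] + config.microbe_sigma * (
        _group_offsets(design, labels, config.effect_size) + noise)

    # structurally rare genera (null, non-cascade) to exercise the filter
    cascade_genus = {s[0] for s in plan["cascades"]}
    eligible = [i for i in range(n_feat)
                if labels[i] == "null" and i not in cascade_genus]
    n_rare = int(round(config.low_prevalence_fraction * n_feat))
    rare = eligible[:n_rare]
    absent = np.zeros((n_feat, n_samp), dtype=bool)
    for i in rare:
        absent[i] = rng.random(n_samp) < 0.45

    A = np.exp(log_abund)
    A[absent] = 0.0
    P = A / A.sum(axis=0, keepdims=True)
    counts = np.column_stack([rng.multinomial(config.depth, P[:, j])
                              for j in range(n_samp)])
    ids = [f"genus_{i:03d}" for i in range(n_feat)]
    counts_df = pd.DataFrame(counts, index=ids, columns=design["sample_id"].tolist())
    taxonomy = pd.DataFrame({
        "genus": ids,
        "phylum": rng.choice(_PHYLA, size=n_feat, p=_PHYLUM_P),
    })
    truth = _truth(plan, config, "microbiome", ids)
    return counts_df, taxonomy, truth


def generate_metabolome(design: pd.DataFrame, config: SimConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Intensity matrix (metabolites x samples, NaN = missing), annotation
    sidecar, ground truth.

    Intensities are log-normal on the log10 scale; dropout is
    missing-not-at-random: the missingness probability is a logistic
    function of the latent log-intensity (low-intensity entries are lost
    preferentially), per group, with maximum probability ``dropout``.
    """
    plan = _plan(design, config)
    labels = plan["metabolome"]["labels"]
    rng = np.random.default_rng([config.seed % (2 ** 31), 22])
    n_feat, n_samp = config.n_metabolites, len(design)
    base = rng.normal(5.0, 1.0, size=n_feat)
    noise = _standardized_noise(plan, "metabolome", _cascade_map(plan, 1),
                                (n_feat, n_samp), rng)
    logI = base[:, None] + config.metabolite_sigma * (
        _group_offsets(design, labels, config.effect_size) + noise)

    dropout = config.dropout if isinstance(config.dropout, dict) else {
        g: config.dropout for g in GROUPS}
    missing = np.zeros((n_feat, n_samp), dtype=bool)
    tau = 0.5 * config.metabolite_sigma
    groups = design["group"].to_numpy()
    for g in GROUPS:
        dmax = dropout.get(g, 0.0)
        if dmax <= 0:
            continue
        cols = groups == g
        block = logI[:, cols]
        c = np.quantile(block, 0.10)
        p_miss = dmax / (1.0 + np.exp((block - c) / tau))
        missing[:, cols] = rng.random(block.shape) < p_miss

    # optional block with >50% missing in exactly one group (forces the filter)
    if config.n_force_missing > 0:
        null_idx = np.flatnonzero(labels == "null")[:config.n_force_missing]
        f1_cols = np.flatnonzero(groups == "F1")
        k = int(np.ceil(0.6 * len(f1_cols)))
        for i in null_idx:
            hit = rng.choice(f1_cols, size=k, replace=False)
            missing[i, hit] = True

    I = 10.0 ** logI
    I[missing] = np.nan
    ids = [f"met_{i:03d}" for i in range(n_feat)]
    intens = pd.DataFrame(I, index=ids, columns=design["sample_id"].tolist())

    rt = rng.uniform(0.0, 0.25, size=n_feat)
    far = rng.random(n_feat) < 0.05
    rt[far] = rng.uniform(0.31, 0.50, size=int(far.sum()))
    n_pw = 20
    pw_ids = [f"pw{j + 1:02d}" for j in range(n_pw)]
    pathways = []
    for _ in range(n_feat):
        k = min(int(rng.poisson(1.0)), 3)
        pathways.append(";".join(sorted(rng.choice(pw_ids, size=k, replace=False)))
                        if k else "")
    annotations = pd.DataFrame({
        "metabolite_id": ids,
        "chemical_class": rng.choice(_CLASSES, size=n_feat, p=_CLASS_P),
        "rt_error": rt,
        "fragmentation_score": rng.uniform(20.0, 80.0, size=n_feat),
        "origin": rng.choice(_ORIGINS, size=n_feat, p=_ORIGIN_P),
        "pathways": pathways,
    })
    truth = _truth(plan, config, "metabolome", ids)
    return intens, annotations, truth


def generate_transcriptome(design: pd.DataFrame, config: SimConfig
                           ) -> tuple[pd.DataFrame, GroundTruth]:
    """Negative-binomial gene count matrix (genes x samples) and ground truth.

    Per-gene log means carry the planted group structure plus biological
    noise; library sizes vary log-normally; counts are NB with the
    configured dispersion (variance = m + dispersion * m^2), Poisson in the
    dispersion -> 0 limit.
    """
    plan = _plan(design, config)
    labels = plan["transcriptome"]["labels"]
    rng = np.random.default_rng([config.seed % (2 ** 31), 23])
    n_feat, n_samp = config.n_genes, len(design)
    base = rng.normal(np.log(200.0), 1.0, size=n_feat)
    noise = _standardized_noise(plan, "transcriptome", _cascade_map(plan, 2),
                                (n_feat, n_samp), rng)
    log_mu = base[:, None] + config.gene_sigma * (
        _group_offsets(design, labels, config.effect_size) + noise)
    sf = np.exp(rng.normal(0.0, 0.3, size=n_samp))
    mu = np.exp(log_mu) * sf[None, :]
    alpha = config.nb_dispersion
    if alpha < 1e-8:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / alpha
        counts = rng.negative_binomial(r, r / (r + mu))
    ids = [f"gene_{i:04d}" for i in range(n_feat)]
    counts_df = pd.DataFrame(counts, index=ids, columns=design["sample_id"].tolist())
    truth = _truth(plan, config, "transcriptome", ids)
    return counts_df, truth


def _truth(plan, config: SimConfig, layer: str, ids: list) -> GroundTruth:
    prefix = {"microbiome": "genus_", "metabolome": "met_", "transcriptome": "gene_"}
    rows = []
    for ci, (gi, mi, ei, lam) in enumerate(plan["cascades"]):
        rows.append({"cascade_id": f"cascade_{ci}",
                     "genus_id": f"genus_{gi:03d}",
                     "metabolite_id": f"met_{mi:03d}",
                     "gene_id": f"gene_{ei:04d}",
                     "loading": lam})
    labels = pd.DataFrame({"feature_id": ids, "layer": layer,
                           "label": plan[layer]["labels"]})
    return GroundTruth(labels=labels, cascades=pd.DataFrame(rows),
                       pattern_counts={layer: plan[layer]["counts"]})


# ---------------------------------------------------------------------------
# Whole-study convenience
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    design: pd.DataFrame
    genus_counts: pd.DataFrame
    taxonomy: pd.DataFrame
    metabolite_intensities: pd.DataFrame
    annotations: pd.DataFrame
    gene_counts: pd.DataFrame
    truth_labels: pd.DataFrame
    truth_cascades: pd.DataFrame


def simulate_study(config: SimConfig | None = None, seed: int | None = None
                   ) -> SimulatedStudy:
    """Generate all three layers plus sidecars for one study."""
    config = config or SimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    design = generate_design(config.n_per_group, config.seed)
    counts, taxonomy, t1 = generate_microbiome(design, config)
    intens, ann, t2 = generate_metabolome(design, config)
    genes, t3 = generate_transcriptome(design, config)
    labels = pd.concat([t1.labels, t2.labels, t3.labels], ignore_index=True)
    return SimulatedStudy(design, counts, taxonomy, intens, ann, genes,
                          labels, t1.cascades)
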