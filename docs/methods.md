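# Methods

This note records the statistical models, the fixed analysis conventions,
the synthetic-data generator's assumptions, and the numerical choices made
in `heterosim`.

## 1. Design and notation

Three groups: parental lines P1 and P2 and their hybrid F1 (display aliases
CC, CR, RR). All feature matrices are features × samples. Per-feature group
values are `x_g` with mean `m_g`, variance `s²_g`, size `n_g`. Defaults
mirror a realistic production-scale trial: n = 91/90/85 per group.

## 2. Mid-parent heterosis

- Mid-parent value `MP = (m_P1 + m_P2)/2`; heterosis rate
  `H% = 100 (m_F1 − MP)/|MP|`. `MP = 0` makes H% undefined and raises.
- Significance of the mid-parent deviation: Welch-style contrast
  `t = (m_F1 − MP)/se`, `se² = s²_F1/n_F1 + s²_P1/(4 n_P1) + s²_P2/(4 n_P2)`,
  with Satterthwaite degrees of freedom. Exactly calibrated for Gaussian
  data on the analysis scale; metabolite H% is computed on log10 contents,
  genes on log2 normalized expression, genera on relative abundances.
- Alternative: a permutation test of the same contrast (group labels
  permuted, `+1` correction, default 999 permutations), for layers where
  normality on the analysis scale is doubtful.

## 3. Pairwise tests and the 12-type pattern classification

Pairwise two-group tests (P1 vs P2, F1 vs P1, F1 vs P2) default to the
Wilcoxon rank-sum: exact when both groups have ≤ 25 observations and no
ties span groups, otherwise the normal approximation with tie and
continuity corrections. Welch's t is available.

The classifier is a total decision table over the three (significance,
direction) outcomes and the group means, at significance level α = 0.05:

1. **Overdominance** — F1 differs significantly from both parents in the
   same direction (`transgressive_high` / `transgressive_low`).
2. **Dominance** — F1 differs from exactly one parent
   (`level_up`/`level_down` by the sign of `m_F1 − MP`).
3. **Additive** — parents differ, F1 lies between them, and F1 either
   differs from both parents in opposite directions or from neither.
4. Everything else is `unclassified`.

Twelve internal type labels (Roman numerals I–XII) subdivide the three
categories ({I, XII} additive; {II, IV, IX, XI} dominance; {III, V, VI,
VII, VIII, X} overdominance) using a fixed symmetric convention on the sign
pattern. A feature is **nonadditive** iff the mid-parent test is
significant *and* the category is dominance or overdominance; on null data
this conjunction is rejected at a rate bounded by α.

## 4. Microbiome community analysis

- **Prevalence filter**: keep a genus iff present (> 0) in strictly more
  than 60 % of samples (pooled; a per-group variant exists).
- **CLR**: per-sample centered log-ratio on proportions; zeros are replaced
  multiplicatively with δ = 0.65 × the smallest non-zero proportion of that
  sample before renormalization. CLR rows sum to zero and are invariant to
  per-sample rescaling.
- **Diversity**: Gini–Simpson `1 − Σ p²` and observed richness;
  group differences by the configured pairwise test.
- **Ordination**: Bray–Curtis dissimilarity; NMDS minimizes Kruskal
  stress-1 by alternating isotonic regression of distances on
  dissimilarity ranks with Guttman (SMACOF) configuration updates;
  classical-MDS initialization plus random restarts (default 4),
  convergence tolerance 1e-7, max 300 iterations.
- **Co-occurrence networks** (per group, ≥ 5 samples): Spearman ρ on CLR
  values; BH-FDR within each network's pair family; an edge requires
  |ρ| > 0.4 **and** q < 0.05, both strict. Topology: density, mean
  clustering coefficient, greedy-modularity communities (networkx).

## 5. Metabolome processing

Fixed order, with a per-stage feature-count audit:

1. **Annotation confidence**: level 1 = |RT error| ≤ 0.3 min and
   fragmentation score ≥ 45; level 2 = |RT error| ≤ 0.3 min, score < 45;
   all other metabolites are dropped.
2. **Missingness**: drop a metabolite if strictly more than 50 % of its
   cells are missing within any one group (NaN = not detected; 0 is an
   observed value).
3. **Imputation**: every missing cell ← 0.5 × the global minimum non-zero
   intensity (one value for the whole matrix) — the standard half-minimum
   convention for left-censored LC-MS data.
4. **log10 + autoscaling**: per-feature mean 0, population-SD 1 (Pareto
   scaling optional). Features with zero variance (relative tolerance
   1e-12) are dropped with a warning.

**PLS-DA** is NIPALS PLS2 against one-hot class indicators with
regression-mode deflation of X and Y; per-component explained Y-variance,
stratified-CV Q², and VIP
`VIP_j = sqrt(p Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)` (mean squared VIP
= 1). **Differential metabolites** per comparison require VIP > 1 (strict,
from a two-class PLS-DA of that comparison) and pairwise-test p < 0.05.
**Origin partition** assigns host/microbiota/other from the annotation's
origin field; co-metabolism counts toward both host and microbiota.

## 6. Transcriptome and integration

- **Normalization**: median-of-ratios size factors (geometric-mean
  reference over genes positive in every sample; library-size fallback with
  a warning), then `log2(count/sf + 1)`.
- **Edge families**: Spearman with BH within family; genus→metabolite and
  metabolite→gene edges need |ρ| > 0.4 and q < 0.05 (strict); the
  metabolite–gene family is restricted to nonadditive genes;
  metabolite–metabolite co-regulation uses |ρ| > 0.6 without an FDR gate
  (q still reported).
- **Cascade triads**: the join of the two cross-layer families on the
  shared metabolite; the triad count is Σ_m deg_genus(m) × deg_gene(m).
- **Enrichment**: one-sided hypergeometric tail `P(X ≥ k)` for k query hits
  among K pathway members, universe N defaulting to the union of all
  pathway members.

## 7. Synthetic-data generator

Defaults are the study conditions (91/90/85 samples; 150 genera, 300
metabolites, 400 genes) and were fixed once, up front.

- **Planted patterns**: per-layer labels drawn multinomially from
  {additive .10, dominance_high .12, dominance_low .12, overdominance_high
  .04, overdominance_low .02, null .60} — dominance-heavy with rare
  transgressive-low, matching the qualitative structure of real heterosis
  surveys. Group offsets in within-group-SD units for (P1, F1, P2):
  null (0,0,0); additive (+e,0,−e); dominance_high (+e,+e,−e);
  dominance_low (+e,−e,−e); overdominance_high (0,+e,0); overdominance_low
  (0,−e,0); default effect size e = 2 SD.
- **Microbiome**: genus log-abundances Normal with base spread 1.5 and
  within-group SD σ = 1.0 (natural log); 10 % of null genera made
  structurally rare (absent with probability 0.45, ~55 % prevalence, to
  exercise the 60 % filter); per-sample closure to proportions and
  multinomial sampling at depth 50 000.
- **Metabolome**: log10 intensities Normal(5, 1) base with within-group SD
  0.5; missing-not-at-random dropout with probability
  `d_max / (1 + exp((x − c)/τ))` per group (c = group 10th percentile,
  τ = 0.5 σ, d_max = 0.2) so low-intensity cells are lost preferentially.
  Annotation sidecar with RT errors (5 % beyond the 0.3-min window),
  fragmentation scores U(20, 80), chemical classes (lipid-heavy),
  origins and semicolon-joined pathway memberships.
- **Transcriptome**: log-mean Normal(ln 200, 1), biological SD 0.8
  (natural log), log-normal(0, 0.3) library-size factors, negative-binomial
  counts with dispersion α = 0.1 (variance m + αm²; Poisson as α → 0).
  These values sit in the typical bulk-RNA-seq range and keep counting
  noise subordinate to biological signal, which is required for cross-layer
  signals to be detectable at realistic correlation thresholds.
- **Cascades**: each triad (genus, metabolite, gene) shares a
  standard-normal latent Z; on the standardized log scale the feature is
  `λZ + sqrt(1−λ²) ε` (unit variance), so two features of one triad have
  cross-layer correlation λ² = 0.81 at the default loading λ = 0.9.
  Cascade hosts are drawn from null-labelled features.
- **Determinism**: all randomness flows from `numpy` Generators seeded with
  `[seed, stream_code]`, so layers can be generated independently yet
  consistently; identical configs give bit-identical tables.

**Realism limits**: no phylogenetic or pathway-level correlation structure
beyond the planted cascades; group variances are homoscedastic; dropout
depends only on intensity; annotation fields are independent of the
planted labels; library composition effects and batch effects are absent.
Conclusions about real-data performance should not be drawn beyond what
these mechanisms cover.

## 8. Numerical choices

- Wilcoxon via `scipy.stats.mannwhitneyu` (vectorized over features);
  all-identical pooled rows return p = 1 by convention.
- Spearman p-values use the t-approximation matching
  `scipy.stats.spearmanr`; constant rows give ρ = NaN and are skipped in
  networks with a warning.
- BH via `statsmodels multipletests(fdr_bh)`; Bray–Curtis via
  `scipy.spatial.distance`; hypergeometric tail via
  `scipy.stats.hypergeom.sf(k−1, N, K, n)`.
- Matrices round-trip through TSV at 12 significant digits; empty cells
  encode missing values and are rejected outside the metabolome layer.
- PLS-DA and NMDS are implemented in-package and verified in the test
  suite against `sklearn` references (`PLSRegression` up to per-component
  sign; nonmetric `MDS` via a shared stress-1 evaluator).

## 9. Limitations

- The 12 Roman-numeral type labels use a fixed internal convention; only
  the three-category groupings are semantically meaningful.
- The mid-parent test's exact calibration holds for Gaussian analysis
  scales; for heavy-tailed layers use the permutation method.
- Cascade discovery joins marginal edge families and does not model
  conditional independence; dense planted effects can produce many triads
  through shared hub metabolites.
- The classifier conditions on three marginal tests without multiplicity
  control across features; downstream summaries report raw fractions.
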