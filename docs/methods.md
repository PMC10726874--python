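# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limits of what the test suite demonstrates.

## Age-association calling (`age_assoc`)

Two tests are run per gene per tissue and a gene is called age-associated
only when both reject at α = 0.05 (configurable; no multiple-testing
correction is applied at this stage, by design — the dual criterion itself
is the filter).

**Partial correlation.** r_ae·s = (r_ae − r_as·r_es)/√((1 − r_as²)(1 − r_es²)),
the Pearson correlation of age and expression with the linear effect of sex
removed from both; p from t = r√(df/(1 − r²)) with df = n − 2. When sex has
no variation the formula degenerates gracefully to plain Pearson r.

**Old-vs-young moderated t.** Samples with 50 ≤ age < 60 are excluded and
expression is regressed on an intercept, an old indicator (age ≥ 60), and
sex. The age term is binary rather than continuous so that β₁ reads
directly as an old-vs-young logFC (a continuous-age mode is available via
`continuous_age=True`); the intercept is included so β₁ does not absorb
baseline expression. Per-gene residual variances are shrunk toward a pooled
prior by the standard empirical-Bayes scheme: the prior df and variance are
moment-matched on log variances via digamma/trigamma inversion, the
posterior variance is (d₀s₀² + df·s²)/(d₀ + df), and the t statistic gains
d₀ extra degrees of freedom. `prior_df=0` disables shrinkage and reproduces
ordinary OLS t exactly (tested to 1e−8). Residual variances and
coefficients within 1e−9 (relative) of zero are snapped to exact zero so a
constant gene reports β₁ = 0, p = 1 rather than noise-driven significance.

**Call direction** is the sign of β₁. Concordance with the partial
correlation's sign is not required; both values are emitted.

**Correlated criteria.** The two null statistics are strongly correlated
(≈ 0.9) because both are linear projections of the same expression noise
onto near-collinear age contrasts. Under the null the dual-criterion call
rate therefore sits well above the α² independence heuristic (empirically
≈ 0.02–0.03 at α = 0.05) while remaining below α; each marginal test is
calibrated at α. This is a property of the method, not an implementation
artifact.

**TSG comparison.** Pearson χ² (df = 1, no continuity correction) on the
2×2 table of {TSG, other} × {age-associated in ≥ 1 tissue, not}.

## Pathway scoring and consensus (`pathway_dys`)

The scorer is a transparent surrogate for topology-aware pathway activation
scoring with the published threshold semantics preserved. Genes sharing a
coexpression-module label are collapsed to their mean logFC and mean
weights; then

score = scale · Σ(w_g · s_g · logFC_g) / Σ(w_g)

with topology weight w_g (default 1), significance weight s_g = 1 for
p < 0.05 else s_relax = 0.1, and scale = 0.1 chosen so that typical
single-gene logFCs of ~1 map well past the ±0.01 activation threshold. The
original algorithm's scale is undocumented; here scale is an explicit free
parameter and the ±0.01 threshold is honored as given.

Per cancer, a pathway is dysregulated when one direction covers ≥ 50% of
*all* that cancer's datasets (not only the dysregulated ones) and strictly
beats the other direction — an exact 50/50 tie is not unidirectional and
yields no call — and the arithmetic mean of the majority-direction scores
passes the threshold. Because each extracted score already exceeds the
threshold, the mean condition is redundant under this extraction convention;
it is kept for fidelity to the stated rule. Process rollup reports, per
parent process, the percentage of its pathways activated/inhibited over the
process's total pathway count. The aging × cancer cross-classification
emits percentages against both denominators (all pathways of the process,
and only the overlapped dysregulated ones), since either reading is
defensible.

## Meta-analysis and prioritization (`meta_rank`)

Stouffer combination uses z_i = Φ⁻¹(1 − p_i/2)·sign(logFC_i) and
Z = Σw_i z_i/√(Σw_i²) with w_i = √(dataset sample size), the classical
weighted choice; boundary p-values are clipped to machine bounds with a
warning. Combined logFC defaults to inverse-variance weighting; a literal
sd-weighted mean (`method="sd_product"`) is retained because the verbal
description of the combination rule is ambiguous. BH FDR is computed with
genes as the family within each cancer (the family is otherwise
unspecified) via `statsmodels.multipletests`. Common-target ordering is
occurrence (desc), then average rank (asc), then gene id for determinism;
the two novelty settings are ranked independently, so the 200 output rows
may contain overlapping genes — the overlap is visible in the output rather
than deduplicated.

## Classification (`target_annot`)

Hallmark mapping is case-insensitive substring matching of keyword lists
against GO term *names* (12 hallmark categories). The age-association
filter keeps a target when it is called in strictly more than
`min_frac · tissue_count` tissues (the smallest qualifying integer at 10%
of 47 tissues is 5) and carries ≥ 1 hallmark. The anti-cancer direction is
the majority sign among cancers with FDR < 0.05 (up ⇒ antagonism, down ⇒
agonism); a curated override table wins when present, covering targets
whose mechanism argues against the expression sign. Group rules: extension
evidence + concordant directions ⇒ 1; extension + opposed or unknown
direction ⇒ 2; shortening only ⇒ 3; no evidence or no effect ⇒ 4.
Contradictory ledgers (extension and shortening evidence for one gene)
resolve to extension with a warning, mirroring how such genes are
conventionally grouped, and are flagged for review. Dual-purpose proposals
are Group-1 minus TSGs, ordered by aging-dysregulated tissue count then
alphabetically.

## Enrichment prediction (`enrich_predict`)

Upper-tail hypergeometric p-values are computed through the stable survival
function; BH FDR is applied across tested terms (k ≥ 1) per query set. The
universe defaults to all genes carrying ≥ 1 biological-process annotation
(configurable). Annotations are flat term sets; no ontology-graph
propagation is performed. The final curation step from nominated
candidates to a short list is judgment-based and out of computational
scope: the full candidate pool is emitted with supporting-term columns.

## Lifespan analysis (`lifespan`)

Kaplan–Meier fitting and the logrank test are delegated to `lifelines`;
the product-limit values are verified against brute-force risk-set
bookkeeping in the tests. The median convention is the smallest observed
day with S(t) ≤ 0.5 (step-function, no interpolation). Biological repeats
are pooled unstratified by default, matching a pooled single-curve
analysis; `stratify_repeats=True` gives the repeat-stratified logrank.
Censoring is supported although the emulated assay observes all deaths.
Median uncertainty is reported as bootstrap percentile intervals (clearly
labeled as such), since the derivation of published ± values on medians is
generally unstated.

## Synthetic data (`synthio`)

The generator's defaults are the study conditions at reduced scale: 8
tissues × 150 donors (ages uniform on [20, 79], both age strata always
populated; sex Bernoulli(1/2), coded 0/1 with an additive effect), 2,000
genes of which 20% carry linear age slopes (0.5 expression units per
decade, 60% negative — most age-associated genes decline), 4 cancers × 3
case-control datasets of 40 + 40 samples with 10% DE genes at |logFC| = 1,
a 135-pathway/27-process hierarchy with 15% of pathways planted per
direction, and lifespan assays of 90 worms per group × 3 repeats with a
+15.8% median shift over a 19-day control median. Expression is Gaussian
on a log-like scale so logFC equals a mean difference, matching the linear
modeling downstream.

Planted pathway directions are realised through membership: 70% of a
planted pathway's genes come from a "core" pool of genes that are both
age-associated and differentially expressed in every cancer with the
matching signs. The core is stratified by aging sign so both directions
are available, and the per-cancer DE sets are the core plus
cancer-specific extras, which also yields the cross-cancer recurrence the
prioritization stage expects. Planted counts are exact
(round(fraction × n)); identical config + seed gives byte-identical
outputs (independent `numpy` generator streams keyed by seed and stage).

Lifespan days follow a Gompertz law with fixed shape 0.3/day and the rate
solved in closed form so the continuous median hits the target; death days
are emitted as continuous values. At 270 animals per arm the KM median has
a standard error of ≈ 0.3 days, so the recovered percent change
concentrates within ±5 points of the planted +15.8%.

What the generator does **not** emulate: count distributions and
library-size artifacts, batch structure, realistic within-pathway
coexpression (module labels are exposed but model nothing), GO-term
semantics, or any correlation between the evidence ledger and expression.
Passing tests therefore demonstrate correctness of the statistical
machinery and the planted-effect recovery properties, not performance on
real GTEx/TCGA-like data.

## Problem sizes and runtime

The test suite and the acceptance script run at desk scale by choice:
recovery uses one tissue of 2,000 genes × 150 samples, one cancer of three
40+40 datasets with 60 pathways, 200 lifespan simulations at 270/arm, and
500–1,000 null logrank simulations at 90/arm. These sizes give Monte Carlo
standard errors comfortably inside the asserted margins.

## Known limitations

- The pathway scorer is a surrogate: scale and relaxed-significance
  constants are free parameters, so absolute score magnitudes are not
  comparable to any published score — only signs and threshold crossings.
- The "≥ 25% zero coverage" filter is applied before normalization; the
  order is configurable but the alternative is untested against a
  reference.
- The VSN step is a calibrated generalized-log surrogate (affine per-sample
  calibration + asinh), not the full maximum-likelihood fit; it preserves
  monotonicity and the large-value log2 limit, which is what downstream
  stages rely on.
- Direction proposals beyond the expression-majority rule (mechanism-based
  judgment) enter only through the explicit override table.
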