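# Methods

This note documents the models, numerical conventions and design choices
behind `integromics`, in the spirit of a statistical-software methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design and data model

The pipeline assumes a feature-by-sample log2-scale expression matrix over
an ordered series of histologic stages (default `P → AT1 → DCIS → CA1D`,
the MCF10A progression panel) with replicate samples per stage (default 3).
Missing cells are flagged on input and **rejected** by every inferential
operation rather than imputed: the design the pipeline targets is complete
triplicates, and silent imputation would change the ANOVA/Tukey degrees of
freedom. All file I/O is tab-separated UTF-8 text with `.` decimals,
written at full double precision so write∘read is the identity to well
below 1e-9.

## Filters

* **Zero-variance filter** — a feature is removed when its sample variance
  is exactly 0 (tolerance 1e-12 on the stored scale, which also absorbs
  float-summation dust in means of identical values). Constant features
  cannot inform any stage contrast.
* **SD-quantile filter** — per-row SD is computed across **all** samples
  (not within triplicate groups): the alternative reading of
  "SD across samples run in triplicate" would discard between-stage signal,
  and the across-all convention reproduces the expected 75% retention
  arithmetic at the quantile cutoff. Sub-tolerance SDs are snapped to zero
  before ranking. The quantile uses linear interpolation between order
  statistics ("type 7", the numpy/R default), pinned for bit-exactness;
  ties at the cutoff are retained (≥, matching "at least the q-quantile").
* **Quantile normalization** — the value of rank r in each column is
  replaced by the mean across columns of the rank-r values; idempotent by
  construction. The sklearn-style `QuantileNormalizer` stores the
  reference distribution at `fit` so held-out samples can be mapped onto it.

## Differential expression

Per feature, a one-way fixed-effects ANOVA (F = MSB/MSW, p from the F
distribution) with Benjamini–Hochberg step-up FDR across all rows
(q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·n/j, capped at 1). Tukey's HSD is computed over all
stage pairs with q = |ȳᵢ − ȳⱼ| / √(MSE/n) (Tukey–Kramer denominator when
unbalanced); transition attribution then uses only the three adjacent
pairs, requiring ANOVA q below the FDR gate, |log2FC| ≥ 2 and Tukey
p < 0.01. "Log fold change of 2" is interpreted as |log2 fold change| ≥ 2
on the log2-scale matrix.

**Degenerate features** (zero pooled within-group variance, which
zero-noise synthetic data produce by construction) yield boundary p-values
— 0 with unequal means, 1 with equal means — under a `RuntimeWarning`
instead of an exception, so exact fixtures flow through the full pipeline.

**Studentized-range SF.** P(Q ≥ q) is computed in-package by
Gauss–Legendre quadrature of

  P(Q ≤ q) = ∫₀^∞ f_s(s) · k ∫ φ(u) [Φ(u) − Φ(u − q·s)]^{k−1} du ds,

with s = √(χ²_ν/ν), 96 outer × 128 inner nodes (absolute error ~1e-14
against independent implementations; the contract is 1e-6). Calls with
more than 512 points use a 1024-point dense grid with monotone PCHIP
interpolation (observed error ~1e-8), which keeps genome-scale Tukey
tables at ~1 s.

**Power at the default thresholds.** With k = 4 stages, n = 3 replicates
and the Tukey p < 0.01 gate, the expected studentized range for a one-step
effect of 4 standard deviations is ≈ 6.93 against a critical value of
≈ 6.20, so per-transition power saturates near two-thirds *regardless of
absolute scale* (the statistic is scale-invariant in effect/noise). The
suite therefore asserts ≥ 90% power at a 6σ step, where the design
actually reaches it, and separately asserts that call counts are monotone
in effect size.

## Progression templates and assignment

The eight templates fix shapes, not magnitudes: G1 (0,1,2,3), G2 (0,1,1,1),
G3 (0,0,1,1), G4 (0,0,0,1) and their sign mirrors G8–G5. Features are
summarized to per-stage means and z-scored (flat profiles are unassignable
and skipped), clustered with K-means (k = 8 by default, k-means++ seeding,
best of 25 restarts, explicit seed), and **clusters** — not individual
features — are matched to templates by Pearson correlation of the centroid
with the shape. The cluster-level rule is deliberate: it mirrors grouping
"to predefined profiles" without inventing per-feature thresholds, and
makes the unassigned bucket ("no consistent pattern") fall out naturally
from sub-0.9 or ambiguous matches. k may exceed the number of populated
patterns safely, since split clusters match the same template; k smaller
than the number of real pattern populations is the harmful direction.

mRNA and pathway assignments use the same group ids with the shape
negated ("reversed semantics"): a G1 gene decreases continuously because
its G1 miRNA repressor increases.

Silhouette scores use Euclidean distance on the z-scored profiles,
s = (b − a)/max(a, b), singletons scoring 0; the 0.5 cutoff is applied to
pathway assignment by default (where cluster quality gates a derived,
set-level signal) and is optional for miRNA/gene assignment.

## PAGE pathway scores

Z = (S̄ₘ − μ)·√m/δ per sample column, with μ, δ the mean and (n−1) SD of
all gene values in the column and m the number of set members present in
the matrix (sets below `min_members = 3` matched members are dropped and
reported). Scores are computed per sample — not per stage contrast — so
the pathway matrix can be clustered and template-assigned exactly like the
gene matrix. Z is invariant under column shift and positive rescaling, and
approximately standard Normal for random sets from an i.i.d. column (the
acceptance script measures the null moments at 10,000 sets).

A consequence worth stating: because every column is standardized by its
own μ and δ, *any* set of measured genes inherits a deterministic trace of
the stage structure (δ grows as stages diverge), so a set can only be
exactly pattern-free if its members are not in the matrix. The synthetic
generator therefore draws its null sets from an unmeasured identifier
namespace — which is also what real MSigDB collections look like against
any single assay, where most members of most sets are absent — keeping
"null" sets truly null at zero noise. Null calibration of PAGE itself is
tested directly with random measured-gene sets.

## Target integration

The per-miRNA lower 5%-quantile context-score cutoff applies to miRNAs
with more than one prediction; single-hit miRNAs are kept, and ties at the
cutoff are kept (a global-cutoff variant is available). Duplicate
(miRNA, gene) rows collapse to the most negative score on input. Family
representatives take the miRNA with the lowest (strongest) total context
score, ties broken lexicographically for determinism. Integration keeps a
predicted pair when both sides carry the same group id; target pathways
additionally require ≥ 1 member overlap with the group's integrated gene
list. Per-transition ranking of target pathways reuses this package's own
score-change + Tukey-adjusted-p ordering rather than an external moderated
linear model; with triplicate pathway scores the two orderings answer the
same question and this keeps the statistical core self-contained.

## Networks and ordering

Edges carry the Pearson r of two entities' per-sample profiles
(miRNA→gene "targets", gene→pathway "member_of"); |r| < 0.7 edges are
dropped (configurable — the correlation-network construction needs *some*
threshold and 0.7 marks conventionally "strong" correlation), constant
profiles are skipped with a warning. Heat-map leaf ordering applies the
Ward update directly to the 1 − r dissimilarity (the "Ward.D" convention
on provided dissimilarities, via scipy's linkage).

## Survival

Median split sends ties to Low (fixed for determinism). The Kaplan–Meier
estimator, the two-group log-rank test (χ² = (O₁−E₁)²/V with the
hypergeometric variance) and the median survival time (first event time
with S ≤ 0.5, undefined if never reached) are implemented directly from
their definitions; lifelines serves as an independent oracle in the test
suite. The Cox model is maximized by Newton iterations on the partial
likelihood via statsmodels' PHReg with the Efron tie approximation
(Breslow via `ties="breslow"`); stage enters as indicators against stage I
and the marker group against High, matching the conventional presentation.
Non-convergence — including monotone likelihood under perfect separation —
raises with diagnostics rather than returning boundary estimates.

## Synthetic-data generator

The generator emulates the motivating study design; its defaults are the
study's printed sizes: 1,983 miRNAs with 1,533 exactly-constant rows (450
informative), 17,708 genes, 4 stages × 3 replicates. 213 miRNAs follow
templates with 83% in the increasing groups and none in G8 (the published
group structure; the exact per-group split is not published, so the
default split (50, 70, 35, 22, 6, 8, 22, 0) was fixed once to respect the
published totals). Gene groups use the published per-group counts
(946, 1751, 452, 166, 248, 299, 1126, 413). Baselines are Uniform(4, 12)
log2 units; template steps are equal across a template's active
transitions at `effect_size` (default 3 log2 units — comfortably above the
|log2FC| ≥ 2 call threshold, as published effect sizes of called features
must be) with additive Gaussian replicate noise (default 0.3 log2 units,
typical of tight cell-line triplicates). The noise model is additive
Gaussian on the log scale because the pipeline operates downstream of
normalization, where ANOVA's assumptions are the natural reference; read-
level count simulation is out of scope.

Target maps give each planted miRNA 2 strong planted targets
(scores Uniform(−1.0, −0.6)) in its own group and 30 weak decoys
(Uniform(−0.2, 0)) against background genes; with ≥ ~20 predictions per
miRNA the per-miRNA 5% quantile sits above the second planted score, so
planted pairs survive the context filter by construction. Enriched gene
sets draw 90% of members from one group's planted genes; null sets
reference unmeasured ids (see the PAGE section). Survival cohorts use
exponential event times with hazard multiplied by exp(β) below the marker
median, Uniform(0, u) censoring with u solved by bisection to the
requested censored fraction, and independent age/stage covariates.

What the generator does **not** emulate — count overdispersion, library-
size effects, correlated features, partially-overlapping real pathway
membership, informative censoring — bounds what passing tests show: they
certify the pipeline's statistical logic and bookkeeping, not robustness
to every artifact of real sequencing data.

`small_config()` is the desk-scale variant used throughout the tests
(8 planted features per template per side, a 600-gene background pool so
the planted fraction stays small relative to the column standardization,
3 enriched sets of size 10 per group). Problem sizes in the test suite and
acceptance script (200 noisy replicates, 10,000 null sets, 5 × 2,000
survival cohorts, 1,500 log-rank nulls) were chosen to pin the Monte-Carlo
error comfortably below the asserted tolerances.

## Known limitations

* Cluster-level template matching inherits K-means' dependence on k and
  seeding; both are explicit, logged parameters, and assignments should be
  read as conditional on them.
* The published end-to-end counts of the motivating study depend on
  deposited sequencing runs, TargetScan 7.1 and MSigDB snapshots; the
  package reproduces the printed *filter arithmetic* and the full workflow
  at the printed scale on synthetic data, not the accession-dependent
  counts themselves.
* PAGE's per-column standardization couples any measured-gene set to the
  global stage structure (see above); interpret weak pathway patterns
  accordingly.
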