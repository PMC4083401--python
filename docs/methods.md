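# Methods

## Scope and model

`coscore` prioritizes candidate biomarkers/targets by the association
between dichotomized gene expression and censored clinical outcomes. The
statistical core is intentionally simple and fully parametric:

* **Expression dichotomy.** Each feature is split into two groups by
  two-cluster k-means in one dimension. We solve this exactly: the optimal
  within-cluster-sum-of-squares 2-partition of scalars is always a threshold
  split of the sorted values, so scanning the n − 1 candidate thresholds
  (restricted to boundaries between *distinct* values, so tied values always
  share a cluster) yields the global optimum with no random initialization
  and no seed dependence. Ties in within-SS between two splits are broken
  toward the larger DOWN (lower) cluster — a deterministic, documented
  convention. The cluster with the higher median expression is UP. Clusters
  with equal medians (possible only in pathological tie patterns) make the
  feature unscorable and it is skipped with a logged reason. The minimum
  cluster size defaults to 1: real cohorts do produce single-sample
  high-expression clusters and the procedure must confront them rather than
  hide them.

* **Survival model.** Each endpoint (overall survival, metastasis) is
  modelled per group as exponential with rate λ under right-censoring. The
  censored MLE is closed form, λ̂ = d/T with d events over total exposure
  T = Σtᵢ, and the maximized log-likelihood is d·(ln(d/T) − 1). The UP/DOWN
  difference is tested by the likelihood ratio of the two-rate model against
  the pooled one-rate model, referred to χ²(1): the natural test for nested
  exponential models, scale-invariant in time (so the heterogeneous units of
  real cohorts do not matter once converted consistently). Its upper tail is
  P_true.

* **CO score.** The null distribution is built by n repetitions (default
  10000) of: remove ⌊0.10·n_samples⌋ samples uniformly without replacement,
  permute the observed UP/DOWN label vector among the retained samples, and
  recompute the same LRT p-value, P*. The score is the empirical permutation
  p-value CO = |{P* ≤ P_true}|/n_effective. The complement 1 − CO is emitted
  alongside so that either orientation ("risk" vs "robustness") of the score
  is available to downstream consumers. Degenerate repetitions (a group
  emptied by removal, or with zero exposure) are dropped from the
  denominator, never imputed.

Because the dichotomy depends on expression only through the optimal
threshold split, CO is invariant under affine transforms of expression
(verified by test); under general monotone transforms the 2-means split may
legitimately move, which is a property of the method, not a defect.

## Design choices where the design was open

* **Exact 2-means instead of Lloyd iterations.** Lloyd's algorithm with
  random initialization can return locally optimal splits and introduces a
  seed sensitivity that would propagate into every downstream score. The
  exact scan removes both problems at O(n log n).
* **LRT rather than Wald or score test** for the two-group comparison: it is
  the standard model-comparison test for nested parametric survival models
  and needs no standard-error approximation at small group sizes.
* **Zero-event groups.** λ̂ = 0 with log-likelihood contribution 0 (the
  supremum of −λT as λ → 0). No continuity correction is added; the LRT
  stays finite, which matters because tiny UP clusters with no events occur
  in practice.
* **Zero follow-up times** are replaced by half the smallest positive time
  (logged); exact zeros otherwise contribute no exposure and can empty a
  group's exposure sum. This is a declared convention.
* **Permutation, not i.i.d. relabelling.** Shuffling the observed label
  vector preserves the UP/DOWN proportions and the exchangeability structure;
  an i.i.d. Bernoulli mode exists behind a flag for sensitivity analysis.
* **P_true on the full sample.** The observed significance is computed once,
  on all samples; only the null repetitions subsample. A per-subsample
  P_true mode (median over removals) is available as a sensitivity option.
* **Removal count** is ⌊0.10·n⌋, drawn fresh per repetition, without
  replacement.
* **Seed policy.** One master seed; each (feature, endpoint) derives a
  31-bit sub-seed by SHA-256 hashing, so scoring results are independent of
  the order in which features are evaluated and stable when features are
  added or removed.
* **Ranking** is by (CO, P_true) ascending: P_true breaks the frequent ties
  at CO = 0 among strong features.
* **CO score orientation.** The defining formula is stated in its source
  only in truncated form; we adopt the empirical-permutation-p-value reading
  (small = strong, robust association) and emit the complement as a second
  column so both orientations are available. This is the largest
  reconstruction in the package and is deliberately prominent here.

## Synthetic cohorts: what they emulate, and what they do not

The generator reproduces the statistical structure the scoring stage
assumes, with defaults at the scale of the meta-analysis setting it stands
in for: 989 samples across three cohorts, 74 candidate features of which 3
are real prognostic targets, survival and metastasis endpoints, follow-up in
months under a 60-month administrative censoring horizon and a baseline
hazard of 0.02 events/month (≈ 70% events by the horizon — an advanced-NSCLC
regime). Per feature, expression is a two-component Gaussian mixture
(separation `mixture_delta` = 2 log2 units, sd 1, high component frequency
`frac_up` = 0.3). The default hazard ratio for true targets is 2.0, a
realistic effect size for a prognostic transcript; no published effect size
exists for the real hits, so this is a free parameter chosen once.

All *true* features share a single latent risk-group assignment that drives
both their expression component and the hazard (baseline × hazard_ratio for
UP). This is the only construction under which several true features can
coexist with the one event time per sample/endpoint that a clinical table
carries; it also mirrors the biology it stands in for (co-regulated markers
of one aggressive phenotype). Null features draw independent mixture labels,
so their expression is independent of outcome by construction.

What the generator does **not** emulate: probe-level and platform effects,
batch structure across cohorts, non-exponential (e.g. decreasing-hazard)
event processes, informative censoring, correlated null features, and
missing clinical fields. Passing tests therefore demonstrate correctness of
the procedure under its own model assumptions and calibration/power in an
idealized regime — not performance on any real cohort.

Event-time units are abstract months; the procedure is scale-invariant for
exponential models. Censoring is administrative (fixed horizon) — the
simplest mechanism that exercises the censored MLE. Randomness is organized
as per-purpose sub-streams (risk labels, per-feature expression, per-endpoint
outcomes, metadata) spawned from the config seed, so changing the feature
count does not shift other features' draws.

## Filters

* **DE thresholds** are strict inequalities at FDR < 0.1 and |log2FC| > 1
  (up-regulation only by default); boundary rows are excluded, and the
  synthetic DE generator plants rows exactly on both boundaries to pin this.
  The exon-level filter collapses qualifying exons to genes; whether the
  fold-change cut applies at exon level is exposed (`require_lfc`, default
  on).
* **Fusion filtering** operates on ordered (5′, 3′) gene pairs: replicate
  intersection, subtraction of any pair seen in *any* wild-type replicate
  (the conservative reading), then artifact classification. Read-through:
  same chromosome and strand, non-overlapping, 5′ partner upstream in
  transcriptional orientation, gap ≤ 200 kb (a declared convention — no
  published rule exists; configurable, with no intervening-gene condition).
  Homologue pair: both partners share a non-empty homology group in the
  annotation; no sequence alignment is performed, keeping the artifact
  self-contained. Calls whose partners are missing from the gene models are
  kept but flagged `unclassifiable`.
* **Harmonization** standardizes heterogeneous per-cohort outcome fields
  into (endpoint, time-in-months, 0/1 event) records via a user-editable
  mapping, with a provenance column naming the raw fields each record came
  from. The test/validation split is by whole cohort on publication year
  (threshold 2009), never within a cohort. Early-stage subsetting keeps one
  TNM T category and counts excluded missing-stage samples.

## Numerical and degenerate-input conventions

* LRT statistics are clipped at 0 (they are non-negative up to rounding; a
  value below −10⁻⁹ raises).
* Constant expression vectors, vectors with < 2 samples, and equal-median
  clusters are degenerate: the feature is skipped and the reason recorded in
  the result's skip table.
* Permutation repetitions are processed in chunks of 2000 to bound the
  (repetitions × samples) work matrices at cohort scale.
* All output tables are ranked deterministically with explicit tie-breaks;
  two runs with identical config and seed are byte-identical, which the test
  suite asserts at file level.

## Problem sizes used in the checks

Calibration uses 200 null features × 200 samples × 500 repetitions (CO
uniformity by Kolmogorov–Smirnov at α = 0.01) and 2000 removals-free
permutations for the tail-frequency check at 0.05. Power/recovery uses 50
replicate cohorts of 300 samples with 2 true targets (hazard ratio 4,
mixture separation 4) among 10 features at 500 repetitions, requiring the
targets to hold the top-2 CO ranks in ≥ 95% of replicates. The analysis
drivers score 74 features × 989 samples at 1000 repetitions. These sizes
were chosen so each property is measured with comfortable statistical margin
while the whole suite stays fast; the null machinery is vectorized across
repetitions, so the reference 10000 repetitions are equally practical.

## Known limitations

* The exponential model's constant-hazard assumption is strong; the score
  inherits any miscalibration of the χ²(1) approximation at very small
  cluster sizes (the permutation null largely absorbs this, which is one of
  its purposes).
* CO values are discrete with resolution 1/n_effective; at small repetition
  counts ties at 0 are common and the secondary P_true ordering matters.
* No multiple-testing correction is applied across features at the scoring
  stage (by design — replication across splits is the error control); users
  screening thousands of features should add one.
* Homology and compartment annotations are input tables; their quality
  bounds the corresponding filters.
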