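# Methods

## Evidence model

A tumor's HRD truth label is derived from its per-gene hit multisets.
For one gene, the recognised hit classes are `germline_pv`,
`somatic_mutation`, `loh`, `promoter_methylation`, `deep_deletion`, and
the status rules are, in precedence order:

1. **deep deletion** — a somatic homozygous deletion is biallelic on its
   own;
2. **germline biallelic** — a germline pathogenic variant co-occurring
   with LOH or a somatic mutation;
3. **methylation biallelic** — promoter methylation plus a somatic
   mutation or LOH;
4. **somatic biallelic** — a somatic mutation plus LOH, or two somatic
   mutation rows in the same gene;
5. **monoallelic** — a lone mutation other than LOH (a germline PV or a
   somatic mutation without a second hit);
6. **none** — no hits, LOH alone, or promoter methylation alone.

Hit order ("first hit" vs "second hit") is not recoverable from a hit
set, so germline biallelic status is declared on co-occurrence. Lone
promoter methylation is deliberately *not* monoallelic: methylation is
not a mutation, and the biallelic-methylation rule requires a second
hit. Two somatic hits are distinguishable only if they were ingested as
two rows; a single somatic row is monoallelic.

A tumor is HRD-true iff any gene reaches a biallelic status. Every
sample carries a second flag computed after discarding methylation hits
(`hrd_truth_no_meth`), emulating cohorts without methylation assays; by
construction it never exceeds `hrd_truth` (removing hits cannot promote
a gene's status, which tests verify by enumeration).

## Classifier evaluation

Scores are compared against the evidence labels. The ROC curve uses
thresholds at unique score values; AUC is the trapezoidal area and
coincides with the tie-aware Mann–Whitney pair-counting probability,
which the tests check by exhaustive pair enumeration at n ≤ 50. The
precision-recall summary uses the step-wise average-precision sum
Σ (Rᵢ − Rᵢ₋₁) Pᵢ rather than nonlinear interpolation, because it is
reproducible and oracle-checkable against an explicit threshold sweep;
this can differ slightly from packages that interpolate between PR
points.

AUC confidence intervals are percentile bootstrap with 2000 replicates
by default, resampling positives and negatives separately so that every
replicate keeps both classes — with 66 ovarian tumors an unstratified
bootstrap occasionally draws single-class resamples. The percentile
interval degenerates when the point AUC approaches 1 (all bootstrap
AUCs equal 1); its coverage is validated in the moderate-separation
regime (population AUC 0.96), where 93/100 simulated intervals cover
the analytic value.

Two correlated AUCs are compared with DeLong's test: per-sample
structural components V₁₀, V₀₁ computed from midranks, their 2×2
empirical covariances pooled as S₁₀/m + S₀₁/n, z = ΔAUC/√var, two-sided
normal p. Identical score vectors (zero variance) report z = 0, p = 1.
The asymptotic p agrees with a stratified paired-bootstrap null of the
AUC difference to within a few hundredths at n = 30.

Positive calls use score ≥ threshold, so the published CHORD cutoff 0.5
calls a score of exactly 0.5 positive; a `strict` flag switches to the
> convention. Accuracy, sensitivity and specificity with a zero
denominator return NaN rather than raising.

## Threshold calibration

Candidate cutoffs are the midpoints between consecutive distinct scores
plus one sentinel below the minimum and one above the maximum (n + 1
candidates for n distinct scores; sentinel offset = half the smallest
positive gap). The fitting criterion defaults to accuracy maximization,
with Youden's J as an alternative; among equally optimal candidates the
smallest cutoff wins, which maximizes sensitivity — the natural
tie-break when the cost of missing an HR-deficient tumor dominates.

Nested cross-validation uses stratified folds (positive counts per fold
differ by at most one), shuffled by the caller's seed; inner-loop seeds
are derived deterministically from it. Each of the 10 outer folds holds
out ~10% of the stratum; the outer-training 90% is split into 10 inner
folds; the best cutoff is fit on each inner-training part (the inner
validation part is unused under accuracy-on-train fitting); the 10
inner cutoffs are averaged; that average is scored on the held-out
outer fold. The reported threshold is the mean of the 10 outer
averages, clamped to the stratum's observed score range (the clamp
exists because sentinel candidates can lie just outside it; in practice
it never binds). The reported accuracy is the mean of the 10 held-out
accuracies; a simulation test confirms it is not optimistic relative to
an independent cohort of equal size. Strata with fewer than 10 members
of either class cannot be stratified tenfold and fail with an explicit
minimum-class-count message (the pipeline logs and skips them).

## Inferential toolkit

**Proportion CIs** default to the continuity-corrected Wilson score
interval (Newcombe's closed form, collapsing to exact bounds at k = 0
and k = n). This method was frozen after verifying it reproduces all
twelve published stratum intervals exactly at one decimal; plain Wilson
and Clopper–Pearson are selectable.

**Partially overlapping samples z-test** (proportions variant, after
Derrick and colleagues): with c paired observations and unpaired blocks
of sizes n₁ − c, n₂ − c,

    z = (p̂₁ − p̂₂) / sqrt( p̄(1 − p̄)(1/n₁ + 1/n₂ − 2φc/(n₁n₂)) )

where p̄ pools both conditions and φ is the phi correlation of the
paired 2×2 table (set to 0 when a margin is empty, c < 2, or variance
is degenerate). With no paired block the statistic reduces exactly to
the classical pooled two-proportion z-test (asserted against
statsmodels). The normal tail is an asymptotic approximation: against a
10⁵-replicate permutation null it agrees to ~0.002 at n = 140 and to
within ~0.05 at n = 60, where the permutation distribution is visibly
discrete.

**Pairwise Fisher tests** use the hypergeometric exact tail per pair of
cancer types with Bonferroni family size = number of pairs (3 for three
cancers). In the pipeline the one-sided directions default to the
benchmark's claims — HRDetect has more unexplained cases than CHORD;
earlier-listed cancer types have fewer unexplained cases than later
ones — and both are caller-overridable.

## Synthetic cohort generator

The generator emulates the marginal structure the analysis assumes, not
tumor biology. Per cancer type it draws an HRD state, per-state scores,
and an evidence pattern:

* **Sizes and prevalence.** Defaults: breast 371, ovary 66, pancreas
  391; evidence prevalence 78/371, 30/66, 55/391 (pooled expectation
  163). Unexplained tumors are genuinely HR-deficient tumors with no
  recorded evidence, so the generative HRD prevalence is
  evidence_prevalence/(1 − unexplained_fraction) — the expected evidence
  counts stay at the published values for any unexplained fraction. The
  default unexplained fraction is 0.15, between the pooled
  default-threshold unexplained rates of the two classifiers (10.9% and
  21.1%).
* **Scores.** Class-conditional Beta distributions — Beta(8,2) for
  HR-deficient, Beta(1,12) for proficient — joined across classifiers by
  a Gaussian copula with latent correlation 0.30, calibrated once by
  numeric sweep so the pooled study-sized Spearman correlation is
  ≈ 0.67. No published within-class dispersion exists; the Beta shapes
  are modelling choices that reproduce the scores' bimodality.
* **Evidence patterns.** Explained HRD tumors draw a gene
  (BRCA1/2-dominated frequencies) and a mechanism: methylation + second
  hit with probability 23/108 in breast/ovary only (restricted to the
  BRCA1 and RAD51C promoters, giving ≈ 23 pooled methylation events),
  otherwise germline + LOH/somatic (70%), somatic + LOH (25%) or deep
  deletion (5%). HR-proficient tumors receive a lone monoallelic hit at
  a background rate (1% breast/ovary, 5% pancreas, mirroring the
  observation that monoallelic hits concentrate in pancreatic tumors).

What passing tests on these cohorts show: the pipeline recovers planted
prevalences, unexplained fractions, analytic AUCs (±0.03) and Bayes
cutoffs (±0.1) under the generative model. What they do not show:
robustness to real-data features the generator omits — within-cancer
score heterogeneity beyond two Beta components, correlated evidence
errors, pathogenicity misclassification, batch effects between source
studies, or cancer types with very few HRD cases.

## Numerical and design choices

* All randomness flows from caller-supplied integer seeds through
  `numpy.random.default_rng`; repeated runs with one seed produce
  byte-identical TSV artifacts and reports.
* Table proportions are reported in percent to one decimal, accuracies
  to two decimals; raw counts are always emitted alongside so every
  printed ratio can be recomputed.
* Degenerate inputs are markers, not crashes: empty strata produce NaN
  proportions, zero-variance tests report their null value with a flag,
  zero-denominator metrics are NaN.
* Default problem sizes (study-sized cohorts of 828, 2000 bootstrap
  replicates, 10×10 nested CV, 10⁵-replicate permutation oracles)
  complete in seconds; tests use the same sizes except the bootstrap
  coverage study (500 replicates × 100 repeats) and the DeLong
  bootstrap oracle (2 × 10⁴ replicates), which keep Monte-Carlo error
  well below their assertion tolerances.

## Known limitations

* The calibrated thresholds of the original study are not reproducible
  without its per-sample scores; calibration is validated by parameter
  recovery on synthetic cohorts instead.
* The inner-loop threshold criterion, fold stratification and seeds of
  the original analysis are unstated; accuracy maximization with
  stratified folds is this package's choice.
* The overlap z-test and DeLong p values are asymptotically normal;
  for very small strata a permutation or exact test would be preferable
  to the normal tail.
* Multiple biallelic genes per tumor are supported, but the generator
  plants at most one biallelic event per tumor; multi-event tumors are
  exercised only in unit tests.
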