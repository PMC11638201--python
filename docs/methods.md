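# Methods

## Disease status and diagnostic criteria

The registry fixes 26 chronic conditions in a canonical order (hypertension
first, then 25 purely self-reported conditions); this order defines the
column order of every matrix in the pipeline. Twenty-five conditions are
taken verbatim from the survey's physician-diagnosis checklist. Hypertension
alone is *derived*: a participant is hypertensive under a criterion iff they
self-report a physician diagnosis **or** SBP ≥ the systolic threshold **or**
DBP ≥ the diastolic threshold. Two conventions are fixed here because
guideline text rarely prints them:

* comparisons are inclusive (≥), the standard guideline reading;
* self-report and measured exceedance combine by logical union — the usual
  epidemiological treatment of "diagnosed or measured" definitions.

Built-in criteria: `CHL2018` (140/90 mmHg) and `ACCAHA2017` (130/80 mmHg);
custom thresholds can be supplied in config. Switching criteria therefore
changes exactly one column of the disease matrix, and the 130/80 column
dominates the 140/90 column element-wise — a monotonicity invariant the
tests enforce on every synthetic cohort.

Derived covariates use half-open bins so every value maps to exactly one
class: BMI [0,18) underweight, [18,24) normal, [24,28) overweight, [28,∞)
obese (Chinese criteria; the printed "18–23.9"/"24–28" labels are resolved
as half-open intervals); central obesity at waist ≥85 cm (men) / ≥80 cm
(women), inclusive; sleep bands [0,7), [7,8], (8,∞) hours; age bands
[·,45), [45,65), [65,∞) for descriptive tables and [·,60), [60,∞) for
subgroup analyses.

## Association: Yule's Q

For each disease pair the exact 2×2 joint counts give
Q = (ad − bc)/(ad + bc). When ad + bc = 0 (a zero cell in both products, or
a zero marginal) Q is undefined; a 0.5 continuity correction is added to all
four cells *for that pair only* (Haldane–Anscombe), keeping Q defined and
strictly inside (−1, 1). Every correction event is logged, since silent
corrections are where sparse-data artifacts would hide. A disease column
that is constant in the analysed sample (nobody or everybody has it) is a
hard error at the full-cohort level — Q carries no information there — and
an automatic, reported exclusion at the stratum level (see below).

## Clustering: Ward on 1 − Q

The dissimilarity is d = 1 − Q (range [0, 2]; diagonal 0). Agglomeration
uses the Lance–Williams recurrence with Ward coefficients
αᵢ = (nᵢ+nₖ)/(nᵢ+nⱼ+nₖ), αⱼ = (nⱼ+nₖ)/(nᵢ+nⱼ+nₖ), β = −nₖ/(nᵢ+nⱼ+nₖ),
γ = 0. Because 1 − Q is not a Euclidean distance, two "dialects" exist and
neither is canonical:

* **default**: the recurrence is applied to d as supplied — equivalent to
  R `hclust(method="ward.D")` (and to the classic `agnes` Ward on
  dissimilarities);
* **`square_dissimilarity=True`**: applied to d² with square-rooted heights —
  equivalent to `hclust(method="ward.D2")` and SciPy's `linkage(..., "ward")`.

The choice is exposed, defaulted and tested against both reference
implementations. Ties in the minimal distance are broken by the
lexicographically smallest (cluster-index, cluster-index) pair, scipy node
numbering, so the merge sequence is fully deterministic. Ward linkage is
reducible, so merge heights are non-decreasing (property-tested).

The number of patterns k is a parameter, default 4, treated as given; merge
heights are reported so users can inspect the cut level. Cluster names
(cardiometabolic, respiratory, digestive-bone-kidney, mental-cancer) are
attached by overlap with configurable seed-disease lists, never by cluster
position; a tie or empty overlap leaves a cluster unnamed.

The test suite verifies the implementation three independent ways: a
closed-form cluster-distance oracle (the identity the Ward recurrence
preserves when d is treated as squared Euclidean), R `hclust` ward.D via
Rscript, and SciPy ward for the squared dialect.

## Pattern analytics

Multimorbidity: ≥2 of the 26 conditions. Pattern multimorbidity: ≥2 of the
pattern's member conditions; by construction pattern flags never exceed
multimorbidity flags. Conventions fixed here:

* **Combination counting** is exact-profile by default: each participant is
  counted once, under the precise member subset they carry (a report that a
  five-disease combination "affects only six patients" only makes sense as
  an exact count). A superset-inclusive `at_least` convention is available
  for sensitivity analyses.
* **Percent bases**: combination frequencies use the full cohort N;
  component-disease shares use the pattern-flagged participants;
  per-disease pattern shares use that disease's carriers; prevalence-table
  rows use the covariate level (row-wise percentages).
* **Rounding** is half away from zero, centralized in one helper:
  1 decimal for prevalence tables, 2 decimals for combination percentages
  (the convention of the tables this machinery reproduces).

## Stratified replication

Strata (sex; age <60/≥60; the five named ethnic groups) are disjoint
sub-cohorts; participants missing the stratifier are dropped with a logged
count. Within each stratum and criterion the full association/clustering
stack is re-run. Two stratum rules are this package's own (how the original
analyses handled sparse strata is not documented anywhere we could follow):

* a disease constant within a stratum is excluded from that stratum's
  clustering and listed in the result;
* strata below a configurable minimum size (default 100) are skipped with a
  warning — Yule's Q on rare diseases in tiny strata is numerically
  meaningless.

Cross-criterion stability is summarized per stratum as the adjusted Rand
index between the two assignments, computed on the diseases clustered under
both. The ARI is implemented in-package (pure pair-count formula) and
cross-checked against scikit-learn in tests.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
any real population. Construction (per participant):

* one standard-normal factor per planted block; disease liability
  L = √ρ·F_block + γ·A + √(1−ρ−γ²)·ε with A the standardized age and γ the
  age gradient (default 0.2 per SD — a realistic prevalence rise with age);
* the flag thresholds L at the standard-normal quantile of the disease's
  target marginal prevalence, so marginals are controlled directly and
  within-block association (tetrachoric ρ, default 0.5) is tuned
  independently;
* four default blocks mirror the four patterns (cardiometabolic including
  hypertension; respiratory; digestive-bone-kidney; mental-cancer); four
  diseases stay unassigned as zero-cross-correlation noise;
* default marginals sit in the few-percent range typical of middle-aged
  survey populations (0.6%–6%); they are stated once and are *not* fitted to
  any published table — the real data are unavailable and no test claims
  marginal-level reproduction;
* blood pressure is bivariate normal (SBP 122±16, DBP 76±10 mmHg,
  correlation 0.5 with the hypertension liability, residual SBP–DBP
  correlation 0.6), placing substantial mass in the 130/80–140/90 band so
  criterion switching genuinely moves participants; DBP is capped 2 mmHg
  below SBP for physiological validity;
* self-reported hypertension fires for a configurable fraction (default
  65%) of the top 18% of the hypertension liability — diagnosed-but-aware
  participants;
* covariates are drawn from fixed categorical distributions approximating a
  rural-majority multi-ethnic northwest-Chinese survey population.

All randomness flows through one seeded generator; the same seed yields a
byte-identical cohort.

What the generator does **not** emulate — and hence what a green test does
not establish: real joint covariate distributions, ethnicity- or
region-specific disease structure, reporting/recall bias, repeated blood
pressure readings, or any survey weighting. Tests on synthetic cohorts
establish that the *pipeline* recovers planted structure and respects its
invariants, not that any real population behaves this way.

## Numerical choices and degenerate inputs

* Yule's Q continuity correction: 0.5 on all four cells, logged, per pair.
* Empty cohorts, all-zero 2×2 tables, k outside [1, n], unknown codes,
  pattern members outside the registry, and empty share denominators are
  explicit errors, never silent NaNs; a disease with zero carriers yields a
  missing (logged) share rather than an error.
* Clip of 1 − Q to [0, 2] guards floating drift at |Q| = 1.
* CSV dialect is fixed (comma, UTF-8, "." decimal); booleans are written as
  0/1 and read case-insensitively from {0,1,true,false,yes,no}; missing
  values stay missing — no imputation anywhere.

## Known limitations

* One blood-pressure reading per participant; averaging of repeats must
  happen upstream.
* No treatment/medication-based hypertension definition.
* No survey weighting or age standardization; no alternative
  pattern-discovery methods (factor analysis, latent class, networks).
* Yule's Q between two *rare* diseases is inherently noisy at realistic
  cohort sizes (a zero joint count pins Q at −1); the clustering is robust
  to this at the default effect sizes, but individual rare-pair Q values
  should not be over-read.
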