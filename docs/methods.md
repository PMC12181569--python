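# Methods

This note documents the statistical model behind `senscan`, the choices
made where the procedure admits more than one reasonable reading, what
the synthetic cohort generator does and does not emulate, and the
numerical conventions of the implementation.

## The analysis

The pipeline estimates the prognostic value of a senescence gene
signature in a merged, multi-dataset microarray survival cohort. Input
samples are MAS5-normalized linear-scale intensity vectors over a probe
set shared across array platforms (in real cohorts, the 22,277-probe
GPL96/GPL570/GPL571 intersection), with per-sample relapse-free survival
(RFS) follow-up and partially missing clinical covariates.

**Scaling normalization.** MAS5 normalizes each array independently, but
datasets differ in overall intensity scale. Each sample *j* is therefore
multiplied by one factor

&nbsp;&nbsp;&nbsp;&nbsp;f<sub>j</sub> = target / mean<sub>p∈shared</sub>(x<sub>pj</sub>),&nbsp;&nbsp;&nbsp;&nbsp;target = 1000,

computed on the shared probes only but applied to every probe. The
operation is exact (post-normalization shared-probe mean equals the
target to float precision), idempotent, and preserves within-sample
probe ratios, so downstream quantities that are ratios or ranks are
untouched.

**Duplicate removal.** Samples deposited in more than one dataset have
identical expression vectors after independent MAS5 runs. Two samples
are treated as duplicates when their shared-probe vectors agree after
rounding to 4 significant figures (bit-exact copies always match; the
rounding only guards against serialization noise). Within a duplicate
group, the copy from the earliest dataset in the supplied priority order
survives; within one dataset the smallest sample id survives, so the
outcome never depends on column order. Detection runs after
normalization, which also collapses copies that differ only by a
dataset scale factor.

**Five-parameter QC.** Per array: background signal, raw Q, percent
present calls, GAPDH/ACTB 3′:5′ ratio (continuous), and bioB spike
detection (binary). A continuous metric passes when it lies within
mean ± 1.96·SD computed across all samples of the merged batch
(population SD); bioB passes iff detected. The documented exclusion
phrase ("failure in one parameter or more than two parameters") does not
parse to a single rule, so both readings are configurable; the default
keeps borderline arrays: ≥ 3 failed metrics → excluded, 1–2 → flagged
but retained, 0 → pass. The band is computed on the merged batch, not
per dataset, because the rule is stated "across all samples" and the
batch is only comparable after normalization.

**Receptor surrogates and subtypes.** ER status is called from probe set
205225_at (ESR1) at a linear-intensity cutoff of 500, HER2/ERBB2 from
216836_s_at at 4800. Intensity exactly at the cutoff calls positive (a
convention; configurable). Progesterone receptor is not called — the
arrays carry no reliable probe set. Surrogate subtypes: ER−/HER2− →
basal, ER−/HER2+ → HER2-enriched, ER+/HER2+ → luminal B, and ER+/HER2−
splits into luminal A/B only when a proliferation marker is supplied
(an optional probe + cutoff, e.g. MKI67; no default cutoff is asserted
because none is established for this surrogate). Without it all
ER+/HER2− samples are luminal A and a warning is logged; subtype counts
in published cohorts cannot be reproduced from ER/HER2 alone.

**Signature score.** The score is the unweighted mean over signature
genes of the per-gene mean of its available probes, on the normalized
linear scale. Gene-then-probe averaging (rather than pooling all probes)
keeps multi-probe genes from being over-weighted; probe pooling is
available behind a flag. Genes with no probe in the matrix are excluded
and reported, never silently dropped. The score is homogeneous of degree
one in the intensities, which is why scoring always follows
normalization.

**The cutoff scan.** To avoid anchoring the survival contrast to one
arbitrary threshold, every distinct observed score value *t* between the
score's lower and upper quartiles is tried as a cutoff (values outside
[Q1, Q3] would produce extreme group imbalance). The split assigns
score > *t* to the high group. Each split is evaluated with a Cox
proportional-hazards model on the binary indicator; the per-cutoff
hazard ratio is oriented hazard(high)/hazard(low), so HR < 1 means
longer survival with high signature expression, and the per-cutoff
p-value is the Wald p from the same model (a log-rank p is available by
flag; Wald is the default so that HR, CI and p come from one fit). The
selected cutoff minimizes p; exact p ties are broken by the strongest
effect, formalized as the largest |log HR| (a direction-symmetric
reading of "strongest hazard ratio"), and residual ties by the smaller
cutoff. The scanned p-value family is Benjamini–Hochberg adjusted; BH is
applied within one scan — adjusting across several signatures is a
separate call. Kaplan–Meier curves and medians for the two groups at the
selected cutoff accompany the result, along with the full (cutoff, p)
series for a significance-vs-cutoff plot.

Minimum-p selection is anti-conservative by construction: under the
global null the unadjusted selected p falls below 0.05 in far more than
5% of replicates (the acceptance suite demonstrates ~25% at n = 200,
and `analysis/06_operating_characteristics.py` reports it alongside the
far better calibrated BH-adjusted q). The selected-cutoff HR is also
biased away from 1 relative to the HR at a pre-specified cutoff; the
reported naive CI is not adjusted for selection, and the Monte-Carlo
experiment quantifies both effects.

**Cox machinery.** Efron tie handling is the default everywhere:
month-resolution survival times guarantee heavy ties. The per-cutoff
fits use a dedicated Newton solver for the single-binary-covariate
partial likelihood in which all quantities reduce to per-event-time
risk-set/tied-event counts of the high group, making each fit O(number
of events) and a full scan of ~10³ cutoffs a sub-second operation
(lifelines fits the same model identically but carries per-fit overhead
that a 10⁴–10⁵-fit simulation study cannot afford; the test suite
cross-checks the two to ≤ 10⁻⁴ and additionally verifies against a
naive textbook likelihood maximized by a derivative-free method).
Non-identifiable splits are detected before iterating: the partial
log-likelihood is concave, so the MLE is finite iff the score function
points inward at ±14 on the log-HR axis; splits failing that check (all
events on one side, or perfect separation) are skipped and logged, and a
scan where every candidate is degenerate (e.g. constant scores) is an
error. The Wald CI uses ±1.96·SE on the log scale; the two-group score
statistic at β = 0 equals the log-rank chi-square on tie-free data,
which the tests assert to 10⁻⁸. Multi-covariate fits (paired models)
delegate to lifelines' `CoxPHFitter` with the same Efron/Newton
scheme; non-convergence and separation raise rather than returning
silent output.

**Paired multivariate models.** Clinical covariates are missing for
large, covariate-specific subsets, so no pooled model is fit by default.
Instead one two-covariate model per clinical factor (signature group +
factor) is fit on the cases complete for that factor, with dropped-case
counts logged. Categorical covariates are reference-coded
(negative/first level; subtype reference = luminal A); age and size
enter continuously. The signature enters as the high/low indicator at
the selected cutoff (consistent with the univariate presentation); a
continuous coding is available. Models with fewer than 10 complete
cases, or with the covariate collinear with the group, are refused with
a diagnostic.

**Cohort summary.** The characteristics table reports, per variable,
counts and one-decimal percentages plus mean ± SD for continuous
variables. Denominators follow the mixed convention of published tables
for these cohorts: event/ER/HER2 percentages are over the total cohort,
node status and subtype over the cases with known values; the convention
is overridable per call. Percentages are audited to recompute exactly
from their own counts.

## The synthetic cohort generator

The generator produces all four pipeline inputs with a recorded ground
truth, so every stage is testable without downloads. Its defaults are
the study conditions of the cohort the pipeline was designed around:
~33% relapse events, ER+ 69.8%, HER2+ 22.8%, node+ 58.4% among the
~68.8% with known nodal status, age ~ N(54.1, 12.5²) years, tumor size
lognormal with mean 2.52 and SD 1.42 cm, administrative follow-up cap at
120 months, and a true high-vs-low signature hazard ratio of 0.66 at the
median score.

*Intensities* are log-normal per probe (median ≈ 500, heavy right
tail). Signature probes share one latent per-sample factor with
probe-specific loadings in [0.3, 0.6] on the log scale — since the
analysis uses only the mean score, a single factor suffices to induce a
controllable score–hazard link. Receptor probes are drawn on the correct
side of their call cutoffs (truncated multiplicative offsets, bounded so
they cannot dominate the shared mean), making realized call fractions
exact Bernoulli draws. The generator first constructs the matrix on the
normalized scale — every sample's shared-probe mean is pinned to exactly
1000 by rescaling the non-receptor shared probes — and then multiplies
by per-dataset scale factors drawn log-uniformly from [0.5, 2]. Scaling
normalization therefore recovers the generated matrix exactly, and the
recorded true score cutoff and high/low grouping coincide with what the
pipeline computes; recovery tests can fit at the true cutoff without a
boundary-mismatch artifact.

*Survival* follows a proportional-hazards model with exponential
baseline (rate 0.0063/month, i.e. baseline median ≈ 110 months; a
Weibull shape is exposed as an option) and linear predictor
log(HR)·1{score > cutoff} (or log(HR) per score SD in linear mode).
Censoring is independent exponential plus the administrative cap; the
censoring hazard is calibrated by root-finding on the closed-form event
probability so the expected event fraction equals the 0.33 target. No
published cohort states its censoring mechanism; independent exponential
censoring is the simplest mechanism compatible with the reported event
fraction, and it implies a median follow-up around 35–40 months — the
generator matches event fraction, not follow-up quantiles.

*Artifacts.* Injected duplicates are exact raw-column copies placed in a
later dataset (clinical and QC rows copied too). QC outliers have three
continuous metrics displaced by 8 SD and the bioB spike undetected —
≥ 3 failures, hence excluded under the default rule even though the
outliers themselves inflate the batch SD.

*What the generator does not emulate*: probe-level cross-correlation
structure of real arrays beyond the single signature factor, batch
effects other than multiplicative scale, informative censoring,
covariate–score dependence (node/age/size are independent of the
signature), and the calendar structure of dataset accrual. Passing tests
therefore show that the pipeline recovers what it assumes — a
log-linear score–hazard link under independent censoring — not that
those assumptions hold in any real cohort.

## Problem sizes and numerical conventions

The analysis drivers simulate one 2006-sample cohort (matching the
merged-database scale) and use 60-replicate Monte-Carlo batches at
n = 600 for recovery and 300–500 replicates at n = 200 for the null
inflation experiment; the test suite uses the same sizes or smaller.
Convergence tolerance for the binary Cox Newton iterations is 10⁻⁹ on
the step, max 50 iterations, steps clipped to ±2 and the coefficient to
|β| ≤ 14 (beyond which a split is declared non-identifiable). Survival
times are rounded to 2 decimals (0.01 month) by default; tests that need
heavy ties round to integers. Duplicate hashing rounds to 4 significant
figures. Unknown clinical values are never imputed anywhere; every
filtering step logs the counts it removes.

## Known limitations

* The naive CI at the selected cutoff is not adjusted for minimum-p
  selection; its true coverage is below nominal and is reported (not
  asserted) by the operating-characteristics driver. Permutation-based
  corrected p-values are out of scope.
* The luminal A/B split requires a proliferation surrogate the
  published criteria do not pin to a probe/cutoff; without one the
  pipeline under-calls luminal B.
* The QC 95% band is a normal-theory tolerance band; with small batches
  (< ~20 arrays) its SD estimate is noisy and the displaced-outlier
  guarantee weakens.
* General multi-covariate fits support Efron ties only (Breslow is
  available on the binary path used by the scan).
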