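# senscan

Prognostic analysis of a senescence gene-expression signature in
merged breast-cancer microarray survival cohorts — implemented as a
tested, reusable pipeline with a fully synthetic cohort generator, so
the entire analysis runs end-to-end without downloading any data.

## The problem

Senescence-associated gene sets (such as the SenMayo list) mark cells in
stable cell-cycle arrest; whether their expression predicts breast
cancer outcome is a question asked of large merged databases: many GEO
cohorts profiled on Affymetrix platforms that share a common probe set,
pooled after per-array MAS5 normalization, with relapse-free survival
(RFS) as endpoint. Answering it requires a chain of unglamorous but
consequential steps — cross-dataset scaling normalization, duplicate
patient removal, array QC, expression-surrogate receptor/subtype calls —
before the statistic of interest: dichotomize the signature's mean
expression at the *best* cutoff between its quartiles, test the split
with Cox regression, and control the multiplicity that optimal-cutoff
selection creates. `senscan` implements that chain for analysts who want
the procedure itself — its operating characteristics, its biases, its
audit trail — rather than one cohort's p-value.

## The statistic

For a per-sample score s (mean over signature genes of per-gene mean
probe intensity, after rescaling every array's shared-probe mean to
1000), the scan considers every distinct cutoff t with Q1 ≤ t ≤ Q3 and
fits the Cox model

&nbsp;&nbsp;&nbsp;&nbsp;h(t·| s) = h₀(t·) · exp(β · 1{s > t}),&nbsp;&nbsp;HR = e^β (high vs low, Efron ties)

selecting the cutoff with minimum Wald p (ties → largest |log HR|, then
lower cutoff) and applying Benjamini–Hochberg across the scanned family.
HR < 1 means longer survival with high signature expression. Minimum-p
selection is intentionally anti-conservative — under the null the
unadjusted selected p is < 0.05 in ~25% of replicates — which is what
the BH step addresses; the package measures this rather than hiding it.
Multivariate adjustment is done in pairs (signature group + one clinical
covariate per model) because clinical covariates are missing for large,
covariate-specific subsets.

## Worked example

The numbered drivers under `analysis/` run the whole study on a
simulated 2006-sample cohort (three datasets, true high-vs-low HR 0.66,
five injected duplicate samples, three injected QC-outlier arrays):

```
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_qc.py
python analysis/03_score_and_subtype.py
python analysis/04_cutoff_scan.py
python analysis/05_multivariate_pairs.py
python analysis/06_operating_characteristics.py
```

With the default seed these print, in order:

```
simulated 2006 samples; realized event fraction 0.337; true cutoff 676.6; ...
2006 samples -> 2001 after removing 5 duplicates -> 1998 after excluding 3 QC outliers (306 flagged but kept)
scored 1998 samples over 25 genes; ER+ 70.3%, HER2+ 23.1%
scanned 998 cutoffs in [517.5, 837.2]; selected 688.2: HR 0.709 (95% CI 0.608-0.827),
  p 1.14e-05, BH q 0.000779; max q across the scan 0.0403
signature p < 0.05 in every paired model: True
```

Reading these: preprocessing removed exactly the five injected
duplicates and three injected outliers (the audit tables in `results/`
name them); the receptor-call fractions match the generator's targets;
the scan found a significant protective association (HR 0.709 near the
true 0.66, high expression → longer survival) that stays below the 5%
FDR at every scanned cutoff; and the signature remains significant in
every paired Cox model. The operating-characteristics driver then
separates estimation from selection: across 60 replicate cohorts the
mean HR at the *true* cutoff is 0.671 with 95.0% CI coverage
(essentially unbiased), while the mean HR at the *selected* cutoff is
0.621 — the selection bias the methods note discusses — and under the
global null 26.3% of replicates reach unadjusted p < 0.05 at the
selected cutoff versus 2.7% after BH adjustment.

Small tables land in `results/` (per-cutoff scan, KM curves, paired
models, cohort characteristics); bulk intermediates and figures go to
`scratch/`. A `senscan` CLI exposes the same stages
(`simulate`/`preprocess`/`annotate`/`scan`/`multivariate`/`report`) for
file-based use; see `senscan --help`.

## Layout

```
src/senscan/        library: types, io, simulate, preprocess, annotate,
                    survival (KM / log-rank / Cox / BH / cutoff scan),
                    multivariate, pipeline, cli
analysis/           numbered narrative drivers (the study, start to end)
tests/              pytest suite incl. brute-force oracles and
                    acceptance checks
scripts/            acceptance.py
docs/methods.md     model, assumptions, design choices, limitations
```
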