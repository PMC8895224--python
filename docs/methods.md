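# Methods

`metabcc` implements the statistical machinery of a case-subcohort
(case-cohort) metabolomics study of an adiposity-like exposure and an
incident disease outcome, together with a synthetic cohort generator so
every stage can be exercised and calibrated without restricted data.
This note records the models, the defaults and why they were chosen,
the numerical choices, and the known limitations.

## Study design and estimand

The design is a case-cohort sample: all incident cases accrued over
follow-up, plus a subcohort drawn as a simple random sample of the full
baseline cohort. Metabolite assays are performed only on this sample.
Exposure–metabolite associations are estimated in the subcohort (a
random sample of the cohort); metabolite–disease hazard ratios are
estimated on the full analysis sample (cases + subcohort) with a
pseudo-likelihood that respects the sampling design. All metabolite
effects are per 1 SD of the log-transformed metabolite; exposure
effects are per 1 SD of the exposure (3.4 kg/m² for the BMI-like
default).

## Metabolite preprocessing

Three forward-only steps, enforced by a `scale_state` guard:

1. **Missingness filter** — a metabolite is dropped if missing
   (below detection) in strictly more than 95% of participants
   (`threshold=0.95`, strict inequality: a metabolite missing in
   exactly 95% is retained).
2. **Detection-limit imputation** — each missing cell is assigned the
   minimum observed intensity of that metabolite. The below-LOD mask is
   kept for provenance.
3. **Log-standardisation** — natural log (base configurable), then
   division by the sample SD (n−1 denominator) so each retained column
   has SD exactly 1. The mean is *not* centred; regression intercepts
   absorb it and per-SD effects are unaffected.

Standardisation uses the full analysis sample by default (HR estimates
are reported per SD in the combined sample); a `sample_subset` argument
allows subcohort-only SDs as a sensitivity analysis. Skewness
diagnostics are emitted but never used to exclude.

## Exposure–metabolite associations

One OLS fit per metabolite: metabolite ~ standardized exposure +
covariates. Covariates follow the primary adjustment set (age
continuous, sex, region 10 levels, education 4 levels, smoking
3 levels, fasting time continuous); categorical covariates expand to
reference-coded indicators with levels sorted lexicographically and the
first level as reference, so codings are bit-for-bit reproducible.
Two-sided p-values use the t distribution with residual degrees of
freedom (at n≈180 the normal approximation is visibly anticonservative).
Benjamini–Hochberg step-up q-values are computed once per model family
(all metabolites tested under one specification; never pooled across
exposures). The per-metabolite fits share one design matrix and are
solved as a single multi-outcome least-squares problem, which is what
makes the metabolome-wide null calibrations (500 replicates × 1000
metabolites) affordable.

## Case-cohort Cox regression

The Prentice pseudo-partial likelihood: at each event time the risk set
is the subcohort members still at risk; a case outside the subcohort
enters only at its own event time. Cases inside the subcohort
contribute as ordinary subcohort members (no double counting). Ties are
handled with the Breslow approximation (event times are continuous in
the generator; ties in real data share a risk set). With the subcohort
equal to the cohort the estimator reduces *exactly* to the standard Cox
partial likelihood — this equivalence, a grid-search oracle on tiny
instances, and lifelines on full-cohort data are the three independent
checks.

Numerics: Newton–Raphson from zero initialisation, up to 50 iterations,
step-halving (≤10 halvings) on any decrease of the pseudo-likelihood;
convergence when max |score| < 1e-8 or the relative log-likelihood
change < 1e-10. Coefficients with |β| > 20 at convergence are flagged as
probable monotone-likelihood (separation). Variance: the default is a
grouped infinitesimal-jackknife (dfbeta) sandwich over subjects — the
pseudo-likelihood is not a true partial likelihood, so the inverse
Hessian alone is not trusted — with the model-based covariance emitted
alongside. Calibration at the emulated study scale (cohort 20 000,
subcohort 180, ~180 cases, true log HR 0.5): mean bias ≈ 0.001 and 95%
CI coverage ≈ 0.94 over 500 replicates.

Left truncation is not implemented (time-in-study scale, entry at 0).
Region enters as a covariate, not a stratification factor, matching the
linear-model adjustment.

## Mendelian randomization

* **Weighted allele score** — sum of effect-allele dosages weighted by
  an external weight table (SD of exposure per allele), after excluding
  SNPs with panel MAF strictly below 1% and SNPs lacking weights
  (itemized exclusions). Dosages are flipped (d → 2−d) when the weight's
  effect allele matches the panel's other allele; an irreconcilable
  allele raises.
* **Stage 1** — OLS of exposure on score + covariates in the large
  cohort subset (emulating a GWAS sample of ~75 000); F = (coef/SE)²,
  incremental R² over covariates.
* **IPD 2SLS** — predicted exposure = stage-1 score coefficient × score
  (covariate components excluded so stage 2 does not double-count
  them); stage 2 regresses the metabolite on predicted exposure +
  covariates in the subcohort. Stage-2 SEs are naive OLS SEs; the
  first-stage sample is two orders of magnitude larger, so its
  uncertainty is negligible, and the choice is flagged in the output.
  A first-stage F below 10 attaches a weak-instrument warning. The
  headline estimate is rescaled per 3.4 kg/m² (1 SD of exposure) by
  post-hoc multiplication; the per-unit coefficient is also emitted.
* **Summary-statistic MR** — IVW (inverse-variance-weighted mean of
  Wald ratios, weights (β_exp/se_out)², fixed-effect SE), MR-Egger
  (weighted regression with intercept, weights 1/se_out², SNPs oriented
  to positive exposure effect, residual dispersion floored at 1), and
  weighted median (50th percentile of the inverse-variance-weighted
  ratio distribution with midpoint interpolation; SE from a seeded
  1000-draw parametric bootstrap). Egger with the intercept forced to
  zero reproduces IVW exactly — a built-in identity check.
* **Cochran's Q** (1 df) compares a genetic and an observational
  estimate of the same contrast.
* **Confounder screen** — each potential confounder regressed on the
  score, with BH q-values within the screen as a multiplicity note.
  No FDR is applied to the MR estimates themselves (unadjusted p-values,
  to avoid over-correction in a screen already restricted a priori).

## Cuboid (Cox–Battey) variable selection

Variables are placed uniformly at random (seeded) on a d1×d2×d3 cuboid;
empty cells are padded with fresh standard-normal noise variables. At
full scale (1153 variables on 11×11×10 = 1210 cells) that is 57 padding
cells — the count follows from the arithmetic and is recorded in the
output rather than fixed a priori. For each of the
d2·d3 + d1·d3 + d1·d2 axis-parallel lines, one joint regression of the
outcome on the line's variables plus fixed covariates is fitted
(case-cohort Cox by default; linear and logistic backends for other
outcomes), giving each variable three z-scores (coefficient / robust
SE). "Indexed by each dimension" is read as axis-parallel lines:
two-dimensional slices would mean ~110-variable joint fits, infeasible
at n≈356.

Selection criteria per line fit: |z| > 2.5 (two-sided — inverse
associations are findings too), rank ≤ 2 by |z|, rank ≤ 3. A variable
is retained under a criterion only if flagged in **all three** of its
fits. Non-convergent line fits contribute z = 0 and no ranks (their
variables cannot be selected from that line); if more than 10% of lines
fail the round aborts. Round 2 re-lays the union of the three round-1
selections on the smallest near-cubic box with sufficient capacity
(e.g. 5×5×5 for 122 survivors), with fresh noise and a fresh seeded
assignment. Nested models accumulate the round-2 selections:
criterion 1; 1 ∪ 2; 1 ∪ 2 ∪ 3. A final joint fit of the covariates plus
the cumulative union yields the coefficient table.

A calibration caveat worth stating plainly: the three z-scores of one
variable are computed from the same data and differ only in the small
random set of co-adjusted columns, so they are strongly dependent
(empirical correlation ≈ 0.96 at n≈356 with 8-variable lines). The
"flagged three times" rule therefore filters false positives far less
than an independence calculation would suggest: the global-null
per-variable selection rate under the |z| > 2.5 criterion is of order
P(|z| > 2.5) ≈ 1e-2, not P(|z| > 2.5)³ ≈ 2e-6. The dedicated
calibration test quantifies this; users should treat the selected sets
as a screening output, not an error-controlled discovery list. With ten
embedded signals at log HR 0.65/SD among 500 variables at n≈356, the
round-2 union recovers on average ≈ 0.9 of them; injected noise columns
are selected in well under 1% of opportunities.

## Discrimination

Risk scores are linear predictors of Prentice Cox fits (base covariate
model, then base + nested biomarker sets — nesting enforced). The
weighted C-index sums, over usable pairs (i an event at t_i, j still at
risk past t_i; pairs tied on event time are unusable), Horvitz–Thompson
pair weights w_i·w_j with concordance credit 1 (correct order) or 0.5
(tied risk). Weights: cases 1, subcohort non-cases 1/sampling_fraction,
so the statistic estimates full-cohort concordance; the unweighted C is
emitted alongside since the reference analysis does not say which it
used. Confidence intervals and the p-value for ΔC against the base
model come from a stratified paired bootstrap (cases and non-case
subcohort members resampled separately, same resample applied to every
model, risk scores held fixed — apparent discrimination, as in the
source analysis; no optimism correction, and that is flagged in the
output). Default 1000 replicates, seeded; the pipeline default of 200
keeps desk-scale runs fast.

## Synthetic cohort generator

The generator reproduces the causal chain the analysis assumes —
allele score → exposure → metabolites → disease — with these defaults:

| parameter | default | rationale |
| --- | --- | --- |
| cohort size | 20 000 | large enough that the subcohort is a ~1% sample |
| SNPs | 100, MAF ∈ (0.05, 0.5) | independent binomial(2, MAF) dosages |
| score R² | 0.011 | variance of exposure explained by the true score |
| exposure | mean 23.9, SD 3.4 kg/m² | BMI-like marginals |
| metabolites | 1208 | panel scale; annotations assign 9 super-pathways |
| exposure-linked | 200 at 0.25 SD/SD (85% positive) | a fifth of the panel responds to adiposity |
| factor loading | 0.39, random sign | pairwise log-intensity correlations with quartiles ≈ ±0.13 |
| hazard-relevant | 10 at log HR 0.65/SD | ln(1.9) per SD, the magnitude class of the strongest markers |
| exposure log HR | 0.25/SD | disease risk rises with adiposity directly too |
| censoring | administrative at 10 y | exponential event times (constant baseline hazard) |
| expected cases | 176 | baseline hazard calibrated numerically (root-finding on the realized log-hazards) unless given explicitly |
| subcohort | 180 | simple random sample, overlapping cases allowed |
| below-LOD | 2% per metabolite | intensities under the per-metabolite quantile are blanked |

Metabolites are generated on the log scale — shared latent factor with
random-sign loadings + exposure term + unit noise + metabolite-specific
location — then exponentiated, so the pipeline's log transform is
exercised non-trivially. A single shared factor cannot make the
*median* pairwise correlation strictly negative (at most half of the
pairs have opposite-sign loadings), so the default structure targets a
median near 0 with quartiles ≈ ∓0.13: within ±0.05 of the −0.036
median, and an IQR spanning it, as observed in metabolome-wide panels.
Hazards use the theoretical (not sample) SD of each causal metabolite,
so the configured log HR per SD is the exact truth.

A master seed drives named substreams (one per component: MAFs,
weights, genotype draws, exposure noise, covariates, loadings, factor,
metabolite noise, event times, subcohort draw, allele flips); a
separate `noise_seed` re-seeds only the realization streams, producing
independent replicates of an identical truth. The emitted weight table
flips the coded allele of a random 10% of SNPs (with the weight sign
adjusted), so allele harmonisation is exercised on every run.

What the generator does **not** emulate: linkage disequilibrium and
population stratification, confounding of the covariates with exposure
or outcome (covariates are independent noise with realistic marginals),
batch/run-day structure, non-proportional hazards, and informative
censoring. Tests passing on this generator therefore validate the
estimators and their calibration under the design assumptions, not
robustness to those violations.

## Pipeline, provenance, determinism

Stage order: simulate/load → qc → associations (exposure; waist; waist
adjusted for exposure) → case-cohort Cox → MR → selection →
discrimination → overlap report. Every emitted table carries a comment
header with the configuration hash (SHA-256 of the canonical config
JSON) and master seed; identical configurations give byte-identical
outputs (asserted in tests). The CLI (`metabcc simulate|qc|assoc|coxcc|
mr|select|discriminate|report|run-all`) is a thin layer over
`metabcc.pipeline`; single-stage subcommands implicitly run the
upstream stages they need in memory and write only their own outputs.

## Problem sizes used in the test suite

Monte-Carlo sample sizes were chosen to give decisive margins at
desk scale: parameter recovery 500 replicates; FDR calibration 500
replicates × 1000 metabolites; 2SLS consistency 200 replicates (the
consistency check uses a deliberately strong instrument, R² = 0.1,
so the mean over 200 replicates is a sharp test; the generator default
stays at 1.1%); selection calibration 50 null + 60 signal replicates at
m = 500; concordance oracle 100 datasets up to n = 500. The acceptance
script re-runs the same computations at the same or slightly reduced
replicate counts and reports the measured values.

## Known limitations

* Barlow-style IPW Cox weighting and stratified baseline hazards are
  out of scope; the Prentice estimator is the only case-cohort Cox.
* Time-varying covariates/effects, competing risks, and left truncation
  are not supported.
* The weighted-median MR SE is a parametric bootstrap, which can be
  optimistic for very few SNPs.
* The selection procedure's false-positive behaviour is screening-grade
  (see the cuboid section); its outputs feed the discrimination stage
  on the same data, so the resulting C-indices are apparent, not
  validated.
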