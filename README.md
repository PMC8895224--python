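# metabcc

Statistical machinery for **case-subcohort metabolomics studies** of an
adiposity-like exposure and an incident disease outcome (e.g. fatty
liver disease): who develops disease, which circulating metabolites
track the exposure, which predict the outcome, and whether the exposure
plausibly causes the metabolite shifts.

The package is aimed at biostatisticians and epidemiologists working
with case-cohort designs, where an expensive assay (a metabolome-wide
panel of ~1200 analytes) is run only on all incident cases plus a small
random subcohort, and standard cohort methods need design-aware
replacements.

## What it implements

* **Metabolite QC** — missingness filter (drop if missing in >95% of
  participants), detection-limit imputation (minimum observed value),
  log-transform and scaling to SD 1.
* **Exposure–metabolome associations** — per-metabolite OLS with
  covariate adjustment, effects in SD of metabolite per 1 SD of
  exposure, and Benjamini–Hochberg FDR per analysis family.
* **Case-cohort Cox regression** — the Prentice pseudo-partial
  likelihood: at each event time the risk set is the subcohort members
  still at risk, and a case outside the subcohort enters only at its
  own event time,

      L(β) = ∏_i  exp(x_i'β) / Σ_{j ∈ R(t_i)} exp(x_j'β),

  maximised by Newton–Raphson with step-halving, with a dfbeta sandwich
  variance. HRs are per 1 SD of metabolite.
* **Mendelian randomization** — externally weighted allele score (MAF
  filter, allele harmonisation), first-stage diagnostics (F,
  incremental R²), individual-level two-stage least squares, and
  summary-statistic IVW / MR-Egger / weighted-median estimators, plus
  Cochran's Q for genetic-vs-observational concordance. Estimates per
  3.4 kg/m² (1 SD) of the exposure.
* **Cuboid (Cox–Battey) variable selection** — predictors laid on an
  11×11×10-style cuboid padded with standard-normal noise, one joint
  regression per axis-parallel line, retention when a variable is
  flagged (|z| > 2.5, top-2, or top-3 by |z|) in all three of its
  fits, repeated for two rounds, yielding nested biomarker sets.
* **Weighted discrimination** — inverse-probability-weighted C-index
  for case-cohort risk models with stratified bootstrap CIs and nested
  model comparison.
* **Synthetic cohorts** — a generator for the full causal chain
  (allele score → exposure → correlated metabolites → proportional-
  hazards incidence → case-subcohort sampling → below-LOD blanking),
  with per-component seed substreams, used by every test.

See `docs/methods.md` for models, defaults, and numerical choices.

## Worked example

```python
from metabcc import (SimConfig, generate_study, qc_pipeline, ModelSpec,
                     fit_linear_assoc, metabolome_wide_cox)

cfg = SimConfig(n_cohort=4000, n_snps=40, n_metab=120, n_bmi_linked=25,
                n_causal_metab=5, subcohort_size=150, target_cases=110,
                seed=42)
study = generate_study(cfg)
metab, _ = qc_pipeline(study.metabolites)          # filter -> LOD -> log/SD

sub = study.study.samples
sub = sub[sub["in_subcohort"]]
assoc = fit_linear_assoc(sub, metab, ModelSpec("bmi", ["age", "sex"]))
print("BMI-associated metabolites (q<0.05):", int((assoc.q < 0.05).sum()))

cox = metabolome_wide_cox(study.study, metab, ModelSpec("bmi", ["age", "sex"]))
top = cox.nsmallest(1, "p").iloc[0]
print(f"top metabolite HR per SD: {top.hr:.2f} ({top.lcl:.2f}, {top.ucl:.2f})")
```

Output:

```
BMI-associated metabolites (q<0.05): 19
top metabolite HR per SD: 2.51 (1.78, 3.54)
```

19 of the 25 truly exposure-linked metabolites are recovered at 5% FDR
with only 150 subcohort members, and the strongest hazard association
is one of the five metabolites the generator wired into the hazard
(truth table in `study.truth`). The
scripts in `examples/` walk through each capability the same way —
simulation, QC, associations, case-cohort Cox, MR, selection,
discrimination — each printing the numbers it computes and what they
mean. A thin CLI mirrors the pipeline:
`metabcc run-all --config cfg.yaml --out results/`.

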