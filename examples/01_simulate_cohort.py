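"""Generate a synthetic case-subcohort study and inspect its structure.

The generator wires up the causal chain the analysis assumes:
allele score -> BMI-like exposure -> metabolites -> disease incidence,
then draws all incident cases plus a random subcohort and blanks
below-detection-limit metabolite cells.
"""

import numpy as np

from metabcc import SimConfig, generate_study

cfg = SimConfig(n_cohort=20_000, n_snps=100, n_metab=300, n_bmi_linked=60,
                n_causal_metab=8, subcohort_size=180, target_cases=176, seed=7)
study = generate_study(cfg)

truth = study.truth
print(f"cohort: {cfg.n_cohort}, realized cases: {truth.attrs['n_cases']}")
print(f"analysis sample (cases + subcohort): {study.study.n}")
print(f"calibrated baseline hazard: {truth.attrs['baseline_hazard']:.2e} /year")
print(f"metabolite matrix: {study.metabolites.values.shape}, "
      f"below-LOD fraction: {study.metabolites.missing_mask.values.mean():.3f}")

g = study.score.to_numpy()
bmi = study.cohort["bmi"].to_numpy()
print(f"score R^2 on exposure: {np.corrcoef(g, bmi)[0, 1]**2:.4f} "
      f"(configured {cfg.score_r2})")
# The truth table records, per metabolite, its exposure effect (SD/SD) and
# its log hazard ratio per SD — the targets every later stage tries to recover.
print(truth.query("is_causal")[["beta_bmi_per_sd", "loghr_per_sd"]].head())
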