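"""Synthetic case-subcohort metabolomics studies.

The generator reproduces the statistical structure the downstream
analysis assumes, as a causal chain:

    allele score -> BMI-like exposure -> metabolites -> disease incidence

* Genotypes are independent binomial(2, MAF) dosages; a weighted allele
  score explains a configurable (small, ~1%) fraction of exposure
  variance.
* Metabolites live on the log scale: a single shared latent factor with
  random-sign loadings induces low/moderate pairwise correlations
  (median near zero, quartiles around +-0.13, emulating a metabolome-
  wide panel); a subset depends linearly on the exposure; everything is
  exponentiated to an intensity scale so the pipeline's log transform is
  exercised non-trivially.
* Disease incidence is proportional-hazards with constant baseline
  hazard: the log hazard is linear in a sparse set of causal metabolites
  (SD units) plus the exposure, with administrative censoring. The
  baseline hazard may be calibrated numerically so the expected case
  count hits a target.
* The analysis sample is all incident cases plus a simple random
  subcohort; below-detection-limit cells are blanked at a per-metabolite
  intensity quantile.

A single master seed drives named substreams (one per component), so
each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize

from .coxcc import CaseCohortStudy
from .mr import DosagePanel
from .preprocess import MetaboliteMatrix

_SUBSTREAMS = (
    "mafs", "genotypes", "weights", "exposure", "covariates", "loadings",
    "factor", "metabolites", "events", "subcohort", "flips",
)


class DegenerateConfigError(ValueError):
    """The configuration cannot produce a usable study."""


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    Defaults describe the emulated study conditions: a cohort of 20 000
    with ~1208 metabolites, a polygenic score explaining 1.1% of the
    variance of a BMI-like exposure (mean 23.9, SD 3.4 kg/m^2), ~200
    exposure-linked metabolites, 10 hazard-relevant metabolites at log HR
    0.65 per SD, ~176 expected cases, and a subcohort of 180.
    """

    n_cohort: int = 20_000
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    score_r2: float = 0.011
    n_metab: int = 1208
    n_bmi_linked: int = 200
    beta_bmi_metab: float = 0.25      # SD of log-metabolite per SD exposure
    metab_factor_loading: float = 0.39
    n_causal_metab: int = 10
    log_hr_per_sd: float = 0.65
    log_hr_bmi: float = 0.25
    baseline_hazard: float | None = None   # None -> calibrated to target_cases
    target_cases: int = 176
    admin_censor_time: float = 10.0
    subcohort_size: int = 180
    lod_quantile: float = 0.02
    exposure_mean: float = 23.9
    exposure_sd: float = 3.4
    target_median_corr: float = -0.036     # documentation of the emulation target
    seed: int = 0
    noise_seed: int | None = None  # fresh realization of the same truth

    def __post_init__(self) -> None:
        if not 0 < self.score_r2 < 1:
            raise ValueError("score_r2 must be in (0, 1)")
        if self.n_bmi_linked > self.n_metab:
            raise ValueError("n_bmi_linked exceeds n_metab")
        if self.n_causal_metab > self.n_metab:
            raise ValueError("n_causal_metab exceeds n_metab")
        if self.subcohort_size > self.n_cohort:
            raise ValueError("subcohort_size exceeds n_cohort")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 1")
        if not 0 <= self.lod_quantile < 1:
            raise ValueError("lod_quantile must be in [0, 1)")


@dataclass
class SyntheticStudy:
    """One generated study plus the ground truth behind it."""

    config: SimConfig
    truth: pd.DataFrame                 # per-metabolite true parameters
    dosages: DosagePanel                # full cohort
    weights: pd.DataFrame               # external-style weight table
    cohort: pd.DataFrame                # full cohort covariates + outcome
    study: CaseCohortStudy              # analysis sample (cases + subcohort)
    metabolites: MetaboliteMatrix       # analysis sample, raw, LOD-blanked
    score: pd.Series                    # true generative score, full cohort


_TRUTH_STREAMS = frozenset({"mafs", "weights", "loadings", "flips"})


def _rngs(seed: int, noise_seed: int | None = None) -> dict[str, np.random.Generator]:
    """Named substreams; truth-defining streams always follow ``seed``.

    With ``noise_seed`` set, realization streams (genotype draws, noise,
    event times, sampling) are re-seeded while the truth (MAFs, weights,
    loadings) stays fixed — giving independent replicates of one truth.
    """
    children = dict(zip(_SUBSTREAMS, np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))))
    if noise_seed is not None:
        noise_children = dict(
            zip(_SUBSTREAMS, np.random.SeedSequence(noise_seed).spawn(len(_SUBSTREAMS)))
        )
        for name in _SUBSTREAMS:
            if name not in _TRUTH_STREAMS:
                children[name] = noise_children[name]
    return {name: np.random.default_rng(c) for name, c in children.items()}


def generate_genotypes(
    n: int, mafs: np.ndarray, seed: int | np.random.Generator = 0
) -> DosagePanel:
    """Independent binomial(2, maf) dosage matrix, one column per SNP."""
    mafs = np.asarray(mafs, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if np.any((mafs <= 0) | (mafs >= 1)):
        raise ValueError("all mafs must lie strictly in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = rng.binomial(2, mafs, size=(n, len(mafs))).astype(np.int8)
    snp_ids = [f"snp{j:04d}" for j in range(len(mafs))]
    sample_ids = pd.RangeIndex(n)
    return DosagePanel(
        dosages=pd.DataFrame(d, index=sample_ids, columns=snp_ids),
        effect_allele=pd.Series("A", index=pd.Index(snp_ids)),
        other_allele=pd.Series("B", index=pd.Index(snp_ids)),
    )


def _covariate_table(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Baseline covariates with realistic marginals; independent of outcome."""
    age = np.clip(rng.normal(50.6, 10.1, n), 30, 79)
    sex = rng.binomial(1, 0.63, n)                       # 1 = female
    region = np.array([f"R{k}" for k in rng.integers(0, 10, n)])
    education = np.array([f"E{k}" for k in rng.choice(4, n, p=[0.35, 0.30, 0.25, 0.10])])
    smoking = np.array([f"S{k}" for k in rng.choice(3, n, p=[0.70, 0.10, 0.20])])
    fasting = rng.uniform(0.5, 12.0, n)
    return pd.DataFrame(
        dict(age=age, sex=sex, region=region, education=education,
             smoking=smoking, fasting_time=fasting)
    )


def expected_case_count(eta: np.ndarray, baseline_hazard: float,
                        censor_time: float) -> float:
    """Expected number of events before administrative censoring.

    Exponential event times: P(event) = 1 - exp(-h0 * exp(eta) * c).
    """
    return float(np.sum(-np.expm1(-baseline_hazard * np.exp(eta) * censor_time)))


def calibrate_baseline_hazard(eta: np.ndarray, target_cases: float,
                              censor_time: float) -> float:
    """Solve for the constant baseline hazard giving the target expected cases."""
    if target_cases >= len(eta):
        raise DegenerateConfigError("target_cases must be below the cohort size")

    def f(log_h):
        return expected_case_count(eta, np.exp(log_h), censor_time) - target_cases

    sol = optimize.brentq(f, -40.0, 10.0)
    return float(np.exp(sol))


def generate_study(config: SimConfig) -> SyntheticStudy:
    """Generate a full synthetic case-subcohort study from a config."""
    cfg = config
    rng = _rngs(cfg.seed, cfg.noise_seed)
    n = cfg.n_cohort

    # --- instrument and exposure ------------------------------------------
    mafs = rng["mafs"].uniform(*cfg.maf_range, cfg.n_snps)
    panel = generate_genotypes(n, mafs, rng["genotypes"])
    w_true = rng["weights"].normal(0.0, 1.0, cfg.n_snps)
    g_raw = panel.dosages.to_numpy(float) @ w_true
    g_std = (g_raw - g_raw.mean()) / g_raw.std(ddof=0)
    z_exp = (
        np.sqrt(cfg.score_r2) * g_std
        + np.sqrt(1.0 - cfg.score_r2) * rng["exposure"].normal(size=n)
    )
    bmi = cfg.exposure_mean + cfg.exposure_sd * z_exp

    covs = _covariate_table(n, rng["covariates"])
    # waist circumference correlated with the exposure (r ~ 0.8)
    wc_noise = rng["covariates"].normal(size=n)
    wc = 79.6 + 10.0 * (0.8 * z_exp + np.sqrt(1 - 0.8**2) * wc_noise)

    # --- metabolites (log scale) ------------------------------------------
    met_ids = pd.Index([f"met{j:04d}" for j in range(cfg.n_metab)], name="metabolite_id")
    signs = rng["loadings"].choice([-1.0, 1.0], cfg.n_metab)
    lam = cfg.metab_factor_loading
    loadings = signs * rng["loadings"].uniform(0.5 * lam, 1.5 * lam, cfg.n_metab)
    beta_raw = np.zeros(cfg.n_metab)
    beta_raw[: cfg.n_bmi_linked] = cfg.beta_bmi_metab * rng["loadings"].choice(
        [-1.0, 1.0], cfg.n_bmi_linked, p=[0.15, 0.85]
    )
    mu = rng["loadings"].uniform(5.0, 10.0, cfg.n_metab)
    # theoretical SD of each log-metabolite (factor + exposure + unit noise)
    sd_log = np.sqrt(loadings**2 + beta_raw**2 + 1.0)

    loghr_per_sd = np.zeros(cfg.n_metab)
    loghr_per_sd[: cfg.n_causal_metab] = cfg.log_hr_per_sd

    factor = rng["factor"].normal(size=n)

    causal = np.flatnonzero(loghr_per_sd != 0)

    def log_metab(cols: np.ndarray, rows: np.ndarray | slice,
                  rng_: np.random.Generator) -> np.ndarray:
        f = factor[rows]
        e = z_exp[rows]
        noise = rng_.normal(size=(len(f), len(cols)))
        return (
            mu[cols]
            + np.outer(f, loadings[cols])
            + np.outer(e, beta_raw[cols])
            + noise
        )

    all_rows = np.arange(n)
    causal_log = log_metab(causal, all_rows, rng["metabolites"])
    causal_z = (causal_log - mu[causal] - 0.0) / sd_log[causal]

    eta = causal_z @ loghr_per_sd[causal] + cfg.log_hr_bmi * z_exp

    # --- event times -------------------------------------------------------
    if cfg.baseline_hazard is None:
        h0 = calibrate_baseline_hazard(eta, cfg.target_cases, cfg.admin_censor_time)
    else:
        h0 = cfg.baseline_hazard
    rates = h0 * np.exp(eta)
    t_event = rng["events"].exponential(1.0 / rates)
    event = t_event <= cfg.admin_censor_time
    event_time = np.minimum(t_event, cfg.admin_censor_time)
    n_cases = int(event.sum())
    if n_cases == 0:
        raise DegenerateConfigError(
            f"no cases generated: baseline_hazard={h0:.3g}, "
            f"admin_censor_time={cfg.admin_censor_time} produce zero incidence"
        )

    # --- case-subcohort sample --------------------------------------------
    subco_idx = rng["subcohort"].choice(n, size=cfg.subcohort_size, replace=False)
    in_subcohort = np.zeros(n, dtype=bool)
    in_subcohort[subco_idx] = True
    in_sample = event | in_subcohort

    cohort = covs.copy()
    cohort["bmi"] = bmi
    cohort["wc"] = wc
    cohort["event_time"] = event_time
    cohort["event"] = event
    cohort["in_subcohort"] = in_subcohort
    cohort.index = pd.Index([f"id{i:06d}" for i in range(n)], name="sample_id")

    panel.dosages.index = cohort.index
    score = pd.Series(g_raw, index=cohort.index, name="score")

    sample_rows = np.flatnonzero(in_sample)
    analysis = cohort.loc[cohort.index[sample_rows]].copy()
    study = CaseCohortStudy(
        samples=analysis, sampling_fraction=cfg.subcohort_size / n
    )

    # --- analysis-sample metabolite intensities ----------------------------
    other = np.setdiff1d(np.arange(cfg.n_metab), causal)
    logm = np.empty((len(sample_rows), cfg.n_metab))
    logm[:, causal] = causal_log[sample_rows]
    logm[:, other] = log_metab(other, sample_rows, rng["metabolites"])
    intensity = np.exp(logm)

    # below-LOD blanking at a per-metabolite intensity quantile
    if cfg.lod_quantile > 0:
        lod = np.quantile(intensity, cfg.lod_quantile, axis=0)
        intensity = np.where(intensity < lod, np.nan, intensity)

    super_pathways = np.array(
        ["Amino Acid", "Carbohydrate", "Cofactors and Vitamins", "Energy",
         "Lipid", "Nucleotide", "Peptide", "Xenobiotics", "Unknown"]
    )
    annot = pd.DataFrame(
        {
            "super_pathway": super_pathways[np.arange(cfg.n_metab) % len(super_pathways)],
            "sub_pathway": [f"sub{j % 40:02d}" for j in range(cfg.n_metab)],
        },
        index=met_ids,
    )
    metab = MetaboliteMatrix(
        values=pd.DataFrame(intensity, index=analysis.index, columns=met_ids),
        annotations=annot,
        scale_state="raw",
    )

    # --- external-style weight table with a fraction of flipped alleles ----
    flip = rng["flips"].random(cfg.n_snps) < 0.10
    weights = pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "effect_allele": np.where(flip, panel.other_allele.values,
                                      panel.effect_allele.values),
            "weight": np.where(flip, -w_true, w_true),
        }
    )

    truth = pd.DataFrame(
        {
            "beta_bmi_per_sd": beta_raw / sd_log,   # SD of metabolite per SD exposure
            "beta_bmi_raw": beta_raw,
            "loghr_per_sd": loghr_per_sd,
            "is_bmi_linked": beta_raw != 0,
            "is_causal": loghr_per_sd != 0,
            "factor_loading": loadings,
            "sd_log": sd_log,
        },
        index=met_ids,
    )
    truth.attrs["log_hr_bmi"] = cfg.log_hr_bmi
    truth.attrs["baseline_hazard"] = h0
    truth.attrs["n_cases"] = n_cases
    truth.attrs["score_r2"] = cfg.score_r2

    return SyntheticStudy(
        config=cfg,
        truth=truth,
        dosages=panel,
        weights=weights,
        cohort=cohort,
        study=study,
        metabolites=metab,
        score=score,
    )


def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["maf_range"] = list(d["maf_range"])
    return d
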