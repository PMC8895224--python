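"""Pipeline orchestration: config, stage sequencing, provenance, reports.

Stage order: simulate (or load) -> qc -> assoc (exposure; waist; waist
adjusted for the exposure) -> coxcc -> mr -> select -> discriminate ->
report. Every emitted table carries a comment header with the config
hash and master seed, and a rerun with an identical config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import ModelSpec, fit_linear_assoc, pathway_summary
from .coxcc import CaseCohortStudy, metabolome_wide_cox
from .cuboid import near_cubic_dims, two_round_selection
from .discrimination import nested_model_comparison
from .mr import (build_weighted_score, confounder_screen, stage1_fit,
                 summary_mr, tsls_fit)
from .preprocess import qc_pipeline
from .simulate import SimConfig, SyntheticStudy, generate_study

ALL_STAGES = ("qc", "assoc", "coxcc", "mr", "select", "discriminate", "report")

DEFAULT_COVARIATES = ["age", "sex", "region", "education", "smoking", "fasting_time"]
DEFAULT_CATEGORICAL = frozenset({"region", "education", "smoking"})


@dataclass
class PipelineConfig:
    """Structured configuration for a full run.

    ``sim`` holds :class:`~metabcc.simulate.SimConfig` overrides; the
    master ``seed`` feeds every stochastic stage. ``stages`` toggles
    which stages run (order is fixed).
    """

    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    sim: dict = field(default_factory=dict)
    exposure: str = "bmi"
    wc_exposure: str = "wc"
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    categorical: list[str] = field(default_factory=lambda: sorted(DEFAULT_CATEGORICAL))
    missing_threshold: float = 0.95
    q_threshold: float = 0.05
    maf_threshold: float = 0.01
    sd_exposure: float = 3.4
    mr_methods: list[str] = field(default_factory=lambda: ["ipd", "ivw", "egger", "wmedian"])
    mr_summary_max: int = 20
    cuboid_dims: list[int] | None = None
    bootstrap_reps: int = 200
    base_model: list[str] = field(
        default_factory=lambda: ["age", "age_sq", "sex", "region", "education",
                                 "smoking", "bmi"]
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance_header(cfg: PipelineConfig, stage: str) -> str:
    return (f"# metabcc stage={stage} config_hash={cfg.config_hash()} "
            f"seed={cfg.seed}\n")


def _emit(df: pd.DataFrame, path: Path, cfg: PipelineConfig, stage: str,
          index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(cfg, stage))
        df.to_csv(fh, sep="\t", na_rep="", float_format="%.10g", index=index)


def read_emitted(path: str | Path, index_col=0) -> pd.DataFrame:
    """Read back a pipeline output table, skipping the provenance header."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def overlap_report(
    assoc_a: pd.DataFrame, assoc_b: pd.DataFrame, q_threshold: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Three-way overlap of q-significant metabolites in two tables."""
    shared = assoc_a.index.intersection(assoc_b.index)
    a_sig = assoc_a.loc[shared, "q"] < q_threshold
    b_sig = assoc_b.loc[shared, "q"] < q_threshold
    flags = pd.DataFrame({"sig_a": a_sig, "sig_b": b_sig,
                          "sig_both": a_sig & b_sig})
    counts = {
        "n_shared": int(len(shared)),
        "n_sig_a": int(a_sig.sum()),
        "n_sig_b": int(b_sig.sum()),
        "n_sig_both": int((a_sig & b_sig).sum()),
    }
    return flags, counts


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: str | Path,
    study: SyntheticStudy | None = None,
) -> dict:
    """Execute the configured stages; returns the in-memory result bundle.

    If ``study`` is None, a synthetic study is generated from
    ``cfg.sim`` with the master seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cat = frozenset(cfg.categorical)
    bundle: dict = {}
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    sub_seed = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]

    if study is None:
        sim_kwargs = dict(cfg.sim)
        sim_kwargs.setdefault("seed", cfg.seed)
        study = generate_study(SimConfig(**sim_kwargs))
    bundle["study"] = study

    samples = study.study.samples.copy()
    samples["age_sq"] = samples["age"] ** 2
    cc_study = CaseCohortStudy(samples=samples,
                               sampling_fraction=study.study.sampling_fraction)

    metab = None
    if "qc" in cfg.stages:
        metab, excl = qc_pipeline(study.metabolites, cfg.missing_threshold)
        bundle["metabolites"] = metab
        bundle["qc_report"] = excl
        _emit(excl, out / "qc_exclusions.tsv", cfg, "qc")

    if metab is None:
        metab, _ = qc_pipeline(study.metabolites, cfg.missing_threshold)
        bundle["metabolites"] = metab

    if "assoc" in cfg.stages:
        spec_bmi = ModelSpec(cfg.exposure, cfg.covariates, cat)
        spec_wc = ModelSpec(cfg.wc_exposure, cfg.covariates, cat)
        spec_wc_bmi = ModelSpec(cfg.wc_exposure, cfg.covariates, cat,
                                extra_adjustment=[cfg.exposure])
        subco = samples.loc[samples["in_subcohort"]]
        assoc_bmi = fit_linear_assoc(subco, metab, spec_bmi)
        assoc_wc = fit_linear_assoc(subco, metab, spec_wc)
        assoc_wc_bmi = fit_linear_assoc(subco, metab, spec_wc_bmi)
        bundle["assoc_bmi"] = assoc_bmi
        bundle["assoc_wc"] = assoc_wc
        bundle["assoc_wc_adj_bmi"] = assoc_wc_bmi
        _emit(assoc_bmi, out / "assoc_bmi.tsv", cfg, "assoc")
        _emit(assoc_wc, out / "assoc_wc.tsv", cfg, "assoc")
        _emit(assoc_wc_bmi, out / "assoc_wc_adj_bmi.tsv", cfg, "assoc")
        _emit(pathway_summary(assoc_bmi, metab.annotations, cfg.q_threshold),
              out / "assoc_bmi_pathways.tsv", cfg, "assoc")

    if "coxcc" in cfg.stages:
        spec = ModelSpec(cfg.exposure, cfg.covariates, cat)
        cox_tab = metabolome_wide_cox(cc_study, metab, spec)
        bundle["cox"] = cox_tab
        _emit(cox_tab, out / "cox_metabolome.tsv", cfg, "coxcc")

    if "mr" in cfg.stages:
        score, excl = build_weighted_score(study.dosages, study.weights,
                                           cfg.maf_threshold)
        cohort = study.cohort
        cov_cols = [c for c in cfg.covariates if c != "fasting_time"]
        cov_df = cohort[cov_cols]
        s1 = stage1_fit(cohort[cfg.exposure], score, cov_df, cat)
        bundle["stage1"] = s1
        screen = confounder_screen(score, cov_df, cat)
        bundle["confounder_screen"] = screen
        _emit(screen, out / "mr_confounder_screen.tsv", cfg, "mr")
        subco_ids = samples.index[samples["in_subcohort"]]
        rows = []
        for met in metab.metabolite_ids:
            y = metab.values.loc[subco_ids, met]
            if "ipd" in cfg.mr_methods:
                est = tsls_fit(y, cohort[cfg.exposure], score,
                               cov_df.loc[cov_df.index.intersection(subco_ids)],
                               sd_exposure=cfg.sd_exposure, categorical=cat,
                               stage1=s1)
                rows.append(dict(metabolite_id=met, method=est.method,
                                 estimate=est.estimate, se=est.se, p=est.p,
                                 egger_intercept=np.nan, egger_intercept_se=np.nan,
                                 stage1_F=s1.f_stat))
        mr_tab = pd.DataFrame(rows).set_index("metabolite_id")
        bundle["mr_ipd"] = mr_tab

        # summary-statistic MR for the strongest exposure-linked metabolites
        summary_rows = []
        want = [m for m in cfg.mr_methods if m in ("ivw", "egger", "wmedian")]
        if want and "assoc_bmi" in bundle:
            top = bundle["assoc_bmi"].nsmallest(cfg.mr_summary_max, "q").index
            bx, bxse = _per_snp_exposure(cohort[cfg.exposure], study, score)
            for met in top:
                by, byse = _per_snp_outcome(metab.values.loc[subco_ids, met],
                                            study, subco_ids)
                for meth in want:
                    try:
                        est = summary_mr(bx, bxse, by, byse, method=meth,
                                         seed=sub_seed[0])
                    except ValueError:
                        continue
                    summary_rows.append(dict(
                        metabolite_id=met, method=est.method,
                        estimate=est.estimate, se=est.se, p=est.p,
                        egger_intercept=est.intercept,
                        egger_intercept_se=est.intercept_se,
                        stage1_F=s1.f_stat))
        mr_sum = (pd.DataFrame(summary_rows).set_index("metabolite_id")
                  if summary_rows else pd.DataFrame())
        bundle["mr_summary"] = mr_sum
        both = pd.concat([mr_tab.reset_index(), mr_sum.reset_index()],
                         ignore_index=True) if len(mr_sum) else mr_tab.reset_index()
        _emit(both.set_index("metabolite_id"), out / "mr_estimates.tsv", cfg, "mr")

    if "select" in cfg.stages:
        dims = tuple(cfg.cuboid_dims) if cfg.cuboid_dims else \
            near_cubic_dims(metab.n_metabolites)
        sel = two_round_selection(cc_study, metab.values, dims,
                                  cfg.covariates, cat,
                                  backend="case-cohort-cox", seed=sub_seed[1])
        bundle["selection"] = sel
        sel_json = {
            "dims_round1": list(sel.assignments[0].dims),
            "dims_round2": list(sel.assignments[1].dims) if len(sel.assignments) > 1 else None,
            "round1": {c: sorted(s) for c, s in sel.round1.items()},
            "round2": {c: sorted(s) for c, s in sel.round2.items()},
            "nested_sets": sel.nested_sets,
            "noise_selected": {c: sorted(s) for c, s in sel.noise_selected.items()},
        }
        with open(out / "selection.json", "w") as fh:
            json.dump({"config_hash": cfg.config_hash(), "seed": cfg.seed,
                       "result": sel_json}, fh, indent=1, sort_keys=True)
        for r, t in enumerate(sel.z_tables, start=1):
            _emit(t, out / f"selection_round{r}_z.tsv", cfg, "select", index=False)
        if sel.final_coefficients is not None:
            _emit(sel.final_coefficients, out / "selection_final_model.tsv",
                  cfg, "select")

    if "discriminate" in cfg.stages:
        sel = bundle.get("selection")
        metab_cols = set(metab.metabolite_ids)
        sets = []
        if sel is not None:
            for key in ("c1", "c1_2", "c1_3"):
                s = [v for v in sel.nested_sets[key] if v in metab_cols]
                if s and (not sets or set(s) != set(sets[-1])):
                    sets.append(s)
        # guarantee nesting after filtering
        nested_ok = all(set(a) <= set(b) for a, b in zip(sets, sets[1:]))
        if not nested_ok:
            sets = [sets[-1]]
        disc = nested_model_comparison(
            cc_study, metab.values, cfg.base_model, sets, cat,
            bootstrap_reps=cfg.bootstrap_reps, seed=sub_seed[2])
        bundle["discrimination"] = disc
        _emit(disc, out / "discrimination.tsv", cfg, "discriminate")

    if "report" in cfg.stages and "assoc_bmi" in bundle and "cox" in bundle:
        flags, counts = overlap_report(bundle["assoc_bmi"], bundle["cox"],
                                       cfg.q_threshold)
        bundle["overlap"] = counts
        _emit(flags, out / "overlap_flags.tsv", cfg, "report")
        with open(out / "overlap_summary.json", "w") as fh:
            json.dump({"config_hash": cfg.config_hash(), "seed": cfg.seed,
                       **counts}, fh, indent=1, sort_keys=True)

    return bundle


def _per_snp_exposure(exposure: pd.Series, study: SyntheticStudy,
                      score: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP OLS of exposure on dosage over the cohort (summary stats)."""
    D = study.dosages.dosages.to_numpy(dtype=float)
    y = exposure.to_numpy(dtype=float)
    return _fast_marginal(D, y)


def _per_snp_outcome(metabolite: pd.Series, study: SyntheticStudy,
                     subco_ids: pd.Index) -> tuple[np.ndarray, np.ndarray]:
    D = study.dosages.dosages.loc[subco_ids].to_numpy(dtype=float)
    y = metabolite.to_numpy(dtype=float)  # already log-standardized post-QC
    return _fast_marginal(D, y)


def _fast_marginal(D: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised simple regressions y ~ each column of D."""
    n = len(y)
    Dc = D - D.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Dc, Dc)
    sxx = np.where(sxx == 0, np.nan, sxx)
    beta = (Dc.T @ yc) / sxx
    resid_ss = np.maximum(yc @ yc - beta**2 * sxx, 0.0)
    se = np.sqrt(resid_ss / (n - 2) / sxx)
    return beta, se
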